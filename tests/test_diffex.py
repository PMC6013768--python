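"""Correction factors, NB GLM/LRT, BH, effect coding, merge and calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

import passportseq.diffex as dx
from passportseq.errors import (
    DegenerateData,
    MissingFactor,
    NoInputSamples,
    PanelMismatch,
)
from passportseq.simulate import SimulationConfig, make_barcode_plan, simulate_counts


def _table(ref, var, cell_line="HEK293", run="run1", snp="rs1"):
    ref = np.asarray(ref, float)
    var = np.asarray(var, float)
    n = len(ref)
    return dx.SnpCountTable(
        snp_id=snp,
        cell_line=cell_line,
        counts=np.concatenate([ref, var]),
        genotype=np.array([0] * n + [1] * n),
        replicate=np.array(list(range(1, n + 1)) * 2),
        run=np.array([run] * 2 * n, dtype=object),
    )


def _counts_frame(snp_rows, sample_ids):
    return pd.DataFrame(snp_rows, columns=sample_ids)


class TestCorrectionFactors:
    def _sheet(self):
        return make_barcode_plan(4, [], 0, seed=1)

    def _factors(self, ref, var):
        sheet = self._sheet()
        counts = pd.DataFrame(
            [ref, var], index=["rs1_REF", "rs1_VAR"], columns=sheet.sample_ids
        )
        return dx.input_correction_factors(counts, sheet)

    def test_identity(self):
        f = self._factors([100, 100, 100, 100], [100, 100, 100, 100])
        assert f["rs1"] == pytest.approx(1.0)

    def test_mean_of_ratios(self):
        # mean(2, 1, 3, 2), NOT ratio of means
        f = self._factors([100, 100, 100, 100], [200, 100, 300, 200])
        assert f["rs1"] == pytest.approx(2.0)

    def test_zero_reference_replicate_dropped(self):
        f = self._factors([0, 100, 100, 100], [50, 100, 100, 100])
        assert f["rs1"] == pytest.approx(1.0)
        assert f.n_used["rs1"] == 3

    def test_all_zero_reference_flagged(self):
        f = self._factors([0, 0, 0, 0], [50, 100, 100, 100])
        assert "rs1" in f.uncomputable
        with pytest.raises(MissingFactor):
            f["rs1"]

    def test_no_input_samples(self):
        sheet = make_barcode_plan(1, ["HEK293"], 2, seed=2)
        cdna = dx.SampleSheet([r for r in sheet if r.role == "cdna"])
        counts = pd.DataFrame(
            [[1] * 2] * 2, index=["rs1_REF", "rs1_VAR"], columns=cdna.sample_ids
        )
        with pytest.raises(NoInputSamples):
            dx.input_correction_factors(counts, cdna)


class TestApplyCorrection:
    def test_factor_one_is_identity_in_both_modes(self):
        t = _table([10, 20], [30, 40])
        factors = dx.CorrectionFactors({"rs1": 1.0}, {"rs1": 4})
        for mode in (dx.MODE_DIVIDE, dx.MODE_OFFSET):
            out = dx.apply_correction(t, factors, mode)
            assert np.allclose(out.counts, t.counts)
            assert np.allclose(out.offset, 0.0)

    def test_divide_halves_variant_offset_is_log(self):
        t = _table([100, 100], [100, 100])
        factors = dx.CorrectionFactors({"rs1": 2.0}, {"rs1": 4})
        div = dx.apply_correction(t, factors, dx.MODE_DIVIDE)
        assert np.allclose(div.counts[div.genotype == 1], 50.0)
        assert np.allclose(div.counts[div.genotype == 0], 100.0)
        off = dx.apply_correction(t, factors, dx.MODE_OFFSET)
        assert np.allclose(off.counts, t.counts)
        # +ln f on the variant observations is the exact analogue of
        # dividing the variant counts by f
        assert np.allclose(off.offset[off.genotype == 1], np.log(2.0))

    def test_divide_and_offset_agree_at_deep_counts(self):
        rng = np.random.default_rng(8)
        factors = dx.CorrectionFactors({"rs1": 1.7}, {"rs1": 4})
        for _ in range(20):
            ref = rng.poisson(5000, 5)
            var = rng.poisson(5000 * 1.7 * 0.8, 5)
            t = _table(ref, var)
            r_div = dx.nb_glm_lrt(dx.apply_correction(t, factors, "divide"), 0.01)
            r_off = dx.nb_glm_lrt(dx.apply_correction(t, factors, "offset"), 0.01)
            assert abs(r_div.log2fc - r_off.log2fc) < 0.02


class TestNbGlmLrt:
    def test_identical_alleles_null(self):
        t = _table([100, 150, 120], [100, 150, 120])
        res = dx.nb_glm_lrt(t, 0.05)
        assert res.log2fc == pytest.approx(0.0, abs=1e-6)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_deep_count_effect_recovery(self):
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(100):
            mu = 5000.0
            ref = rng.poisson(mu, 5)
            var = rng.poisson(mu * 2 ** -0.5, 5)
            ests.append(dx.nb_glm_lrt(_table(ref, var), 0.0).log2fc)
        assert np.mean(ests) == pytest.approx(-0.5, abs=0.05)

    def test_matches_exact_binomial_at_zero_dispersion(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            mu = 800.0
            fc = rng.choice([1.0, 0.9, 1.1])
            ref = rng.poisson(mu, 5)
            var = rng.poisson(mu * fc, 5)
            res = dx.nb_glm_lrt(_table(ref, var), 0.0)
            p_oracle = binomtest(int(var.sum()), int(var.sum() + ref.sum()), 0.5).pvalue
            assert abs(res.p_value - p_oracle) <= 0.02

    def test_zero_allele_continuity_rule(self):
        res = dx.nb_glm_lrt(_table([50, 60, 70], [0, 0, 0]), 0.05)
        assert res.zero_allele
        assert np.isfinite(res.log2fc) and res.log2fc < -3
        assert 0 < res.p_value < 1

    def test_run_covariate_absorbs_depth_difference(self):
        a = _table([1000, 1100], [1000, 1100], run="A")
        b = _table([100, 110], [100, 110], run="B")
        merged = dx.merge_runs(a, b)
        res = dx.nb_glm_lrt(merged, 0.0)
        assert res.log2fc == pytest.approx(0.0, abs=1e-6)


class TestDispersionEstimation:
    def _tables(self, phi, n_snps=150, seed=0, mu=1000.0):
        rng = np.random.default_rng(seed)
        tables = []
        for i in range(n_snps):
            if phi == 0:
                ref = rng.poisson(mu, 5)
                var = rng.poisson(mu, 5)
            else:
                r = 1 / phi
                ref = rng.negative_binomial(r, r / (r + mu), 5)
                var = rng.negative_binomial(r, r / (r + mu), 5)
            tables.append(_table(ref, var, snp=f"s{i}"))
        return tables

    def test_poisson_counts_give_near_zero_common_dispersion(self):
        est = dx.estimate_dispersion(self._tables(0.0), tagwise=False)
        assert est.phi_common <= 0.05

    def test_recovers_true_dispersion(self):
        for seed in range(3):
            est = dx.estimate_dispersion(
                self._tables(0.1, n_snps=100, seed=seed), tagwise=False
            )
            assert 0.05 <= est.phi_common <= 0.2

    def test_shrinkage_weight_formula(self):
        tables = self._tables(0.1, n_snps=30, seed=4)
        est = dx.estimate_dispersion(tables, n_prior=10.0)
        assert est.shrinkage_weight == pytest.approx(10 / 15)
        # every tagwise value is the stated convex combination, hence
        # within (1-w) * |mle - common| of the common value
        for snp, phi_s in est.phi_snp.items():
            mle = dx._mle_phi([t for t in tables if t.snp_id == snp])
            expected = est.shrinkage_weight * est.phi_common + (1 / 3) * (
                0.0 if mle <= 1e-7 else mle
            )
            assert phi_s == pytest.approx(expected, rel=0.05, abs=5e-3)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateData):
            dx.estimate_dispersion([_table([0, 0], [0, 0])])


class TestBhAdjust:
    @staticmethod
    def brute_force(p):
        """Step-up from the definition: q_i = min over ranks >= rank_i of
        p_(j) * m / j, capped at 1."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranks = np.empty(m, int)
        ranks[order] = np.arange(1, m + 1)
        q = np.empty(m)
        for i in range(m):
            q[i] = min(
                min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]),
                1.0,
            )
        return q

    def test_hand_example(self):
        q = dx.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert dx.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(dx.bh_adjust(p), self.brute_force(p))

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(14)
        p = rng.random(500)
        q = dx.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(DegenerateData):
            dx.bh_adjust([])


class TestEffectCoding:
    @pytest.mark.parametrize(
        "log2fc,pct,category",
        [
            (1.0, 100.0, "+++"),
            (0.0, 0.0, "0"),
            (np.log2(0.88), -12.0, "--"),
            (np.log2(1.07), 7.0, "+"),
            (np.log2(0.96), -4.0, "0"),
            (np.log2(0.85), -15.0, "---"),
            (np.log2(1.10), 10.0, "++"),
        ],
    )
    def test_percent_and_category(self, log2fc, pct, category):
        assert dx.percent_change(log2fc) == pytest.approx(pct, abs=1e-9)
        assert dx.categorize(dx.percent_change(log2fc)) == category


class TestMergeRuns:
    def test_duplicate_run_copy_reproduces_single_run_estimate(self):
        rng = np.random.default_rng(15)
        ref = rng.poisson(2000, 5)
        var = rng.poisson(1800, 5)
        single = dx.nb_glm_lrt(_table(ref, var, run="A"), 0.01)
        merged = dx.merge_runs(_table(ref, var, run="A"), _table(ref, var, run="B"))
        both = dx.nb_glm_lrt(merged, 0.01)
        assert both.log2fc == pytest.approx(single.log2fc, abs=1e-6)

    def test_mismatched_snp_rejected(self):
        with pytest.raises(PanelMismatch) as exc:
            dx.merge_runs(_table([1], [1], snp="a", run="A"), _table([1], [1], snp="b", run="B"))
        assert set(exc.value.snp_ids) == {"a", "b"}

    def test_different_depths_same_effect(self):
        rng = np.random.default_rng(16)
        truth = 2 ** -0.4
        a = _table(rng.poisson(4000, 5), rng.poisson(4000 * truth, 5), run="A")
        b = _table(rng.poisson(400, 5), rng.poisson(400 * truth, 5), run="B")
        res = dx.nb_glm_lrt(dx.merge_runs(a, b), 0.0)
        assert res.log2fc == pytest.approx(-0.4, abs=0.1)


class TestCallFunctional:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "cell_line", "fdr"])

    def test_union_and_triple_intersection(self):
        rows = [("s1", cl, 0.01) for cl in ("A", "B", "C")]
        rows += [("s2", cl, 0.5) for cl in ("A", "B", "C")]
        summary = dx.call_functional(self._results(rows))
        assert summary.union == 1
        assert summary.intersections[("A", "B", "C")] == 1
        assert summary.per_cell_line == {"A": 1, "B": 1, "C": 1}

    def test_nothing_significant(self):
        rows = [("s1", cl, 0.9) for cl in ("A", "B")]
        summary = dx.call_functional(self._results(rows))
        assert summary.union == 0 and summary.per_cell_line == {"A": 0, "B": 0}

    def test_planted_cell_specific_effects_recovered(self):
        cfg = SimulationConfig(
            n_snps=40, mean_reads=20000.0, dispersion=0.01,
            frac_nonnull=0.4, effect_log2fc=1.0, seed=17,
        )
        counts, sheet, truth = simulate_counts(cfg)
        results = dx.run_experiment(counts, sheet)
        summary = dx.call_functional(results)
        truth_df = truth.to_frame()
        strict = dx.call_functional(results, fdr_threshold=1e-6)
        for cl in cfg.cell_lines:
            planted = set(truth_df[(truth_df.cell_line == cl) & ~truth_df.null]["snp_id"])
            # deep counts + |log2fc|=1: every planted effect is found;
            # at FDR 1e-6 nulls cannot sneak in, so the sets match exactly
            assert planted <= summary.sets[cl]
            assert strict.sets[cl] == planted


class TestRunExperiment:
    def test_output_schema_and_fdr_pooling(self):
        cfg = SimulationConfig(n_snps=15, seed=18)
        counts, sheet, _ = simulate_counts(cfg)
        res_all = dx.run_experiment(counts, sheet)
        assert len(res_all) == 15 * 3
        assert set(["snp_id", "cell_line", "log2fc", "percent_change",
                    "p_value", "fdr", "functional", "category"]) <= set(res_all.columns)
        np.testing.assert_allclose(
            res_all["fdr"], dx.bh_adjust(res_all["p_value"].to_numpy())
        )
        res_per = dx.run_experiment(counts, sheet, bh_pool="per-cell-line")
        for cl in res_per["cell_line"].unique():
            sub = res_per[res_per["cell_line"] == cl]
            np.testing.assert_allclose(sub["fdr"], dx.bh_adjust(sub["p_value"].to_numpy()))

    def test_sign_consistency_invariant(self):
        cfg = SimulationConfig(n_snps=25, seed=19)
        counts, sheet, _ = simulate_counts(cfg)
        res = dx.run_experiment(counts, sheet)
        assert (np.sign(res["percent_change"]) == np.sign(res["log2fc"])).all()
        assert (res.loc[res["functional"], "fdr"] <= 0.05).all()
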