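"""Differential expression engine for allele-resolved reporter counts.

The model
---------
For each SNP and cell line, read counts :math:`y` from the reference and
variant alleles across biological replicates follow a negative binomial
distribution with mean :math:`\\mu` and variance
:math:`\\mu + \\varphi\\mu^2` (dispersion :math:`\\varphi \\ge 0`; the
Poisson limit at :math:`\\varphi = 0`). A log-link GLM regresses counts
on an intercept, replicate indicators (and run indicators when merging
sequencing runs), and a genotype indicator (variant = 1):

.. math:: \\log \\mu = X\\beta + o

The genotype coefficient divided by :math:`\\ln 2` is the log2
fold-change of the variant allele relative to the reference allele. The
p-value comes from a likelihood-ratio test on the genotype term: the
difference of deviances between the reduced (no genotype) and full
models, referred to a chi-square distribution with 1 degree of freedom.
Replicate indicators absorb per-well depth because both alleles of a
SNP are sequenced out of the same well; no between-sample normalization
is applied.

Input correction
----------------
The transfected plasmid pool is not perfectly balanced between alleles.
A per-SNP correction factor :math:`f` is estimated from sequenced
input-plasmid replicates as the mean over replicates of
(variant reads / reference reads). Correction is applied either by
dividing the variant counts by :math:`f` (``mode="divide"``, the
default; the NB likelihood handles the resulting non-integer working
counts through its gamma-function continuous extension) or by giving
variant observations a model offset :math:`+\\ln f`
(``mode="offset"``, the statistically exact equivalent of dividing).

Dispersion
----------
A common dispersion is estimated by maximizing the NB profile
log-likelihood summed over SNPs, with the replicate+genotype means
profiled out; per-SNP maximum-likelihood dispersions are shrunk toward
it with a fixed prior weight ``n_prior / (n_prior + n_replicates)``.

Multiple testing pools all (SNP x cell line) p-values of an experiment
through the Benjamini-Hochberg step-up procedure; a SNP is called
functional in a cell line when its FDR is at or below the threshold
(default 0.05). Effects are additionally reported as percent change
``(2^log2fc - 1) * 100`` and coded into signed magnitude categories:
|pct| < 5 -> "0"; 5-10 -> "-"/"+"; 10-15 -> "--"/"++"; >= 15 ->
"---"/"+++".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import (
    DegenerateData,
    MissingFactor,
    NoInputSamples,
    PanelMismatch,
    TooFewReplicates,
)
from .readproc import SampleSheet

MODE_DIVIDE = "divide"
MODE_OFFSET = "offset"

_PHI_MIN = 1e-8
_PHI_MAX = 5.0


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------
@dataclass
class CorrectionFactors:
    """Per-SNP variant/reference input-pool imbalance factors."""

    factor: dict[str, float]
    n_used: dict[str, int]
    uncomputable: set[str] = field(default_factory=set)

    def __getitem__(self, snp_id: str) -> float:
        try:
            f = self.factor[snp_id]
        except KeyError:
            raise MissingFactor(f"no correction factor for {snp_id!r}") from None
        if not math.isfinite(f):
            raise MissingFactor(f"correction factor for {snp_id!r} is uncomputable")
        return f


@dataclass
class SnpCountTable:
    """Paired ref/var observations for one SNP in one cell line.

    Arrays are aligned: observation i has count ``counts[i]``, genotype
    ``genotype[i]`` (0 = reference, 1 = variant), replicate and run
    labels, and a model offset (0 unless offset-mode correction is in
    force). ``corrected`` marks divide-mode tables.
    """

    snp_id: str
    cell_line: str
    counts: np.ndarray
    genotype: np.ndarray
    replicate: np.ndarray
    run: np.ndarray
    offset: np.ndarray | None = None
    corrected: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=int)
        self.replicate = np.asarray(self.replicate)
        self.run = np.asarray(self.run)
        if self.offset is None:
            self.offset = np.zeros_like(self.counts)
        else:
            self.offset = np.asarray(self.offset, dtype=float)
        n = len(self.counts)
        if not (len(self.genotype) == len(self.replicate) == len(self.run) == n):
            raise ValueError(f"{self.snp_id}: misaligned observation arrays")

    @property
    def n_replicates(self) -> int:
        return len({(r, u) for r, u in zip(self.replicate, self.run)})

    def design(self, with_genotype: bool = True) -> np.ndarray:
        """Intercept + replicate dummies (+ run dummies) (+ genotype)."""
        cols = [np.ones(len(self.counts))]
        rep_levels = sorted(set(self.replicate.tolist()))
        for level in rep_levels[1:]:
            cols.append((self.replicate == level).astype(float))
        run_levels = sorted(set(self.run.tolist()))
        for level in run_levels[1:]:
            cols.append((self.run == level).astype(float))
        if with_genotype:
            cols.append(self.genotype.astype(float))
        return np.column_stack(cols)


@dataclass
class DispersionEstimate:
    phi_common: float
    phi_snp: dict[str, float]
    shrinkage_weight: float
    n_prior: float = 10.0

    def for_snp(self, snp_id: str) -> float:
        return self.phi_snp.get(snp_id, self.phi_common)


@dataclass
class GlmResult:
    snp_id: str
    cell_line: str
    log2fc: float
    lrt_stat: float
    p_value: float
    converged: bool = True
    zero_allele: bool = False


# --------------------------------------------------------------------------
# input correction
# --------------------------------------------------------------------------
def input_correction_factors(
    counts: pd.DataFrame, sheet: SampleSheet, run: str | None = None
) -> CorrectionFactors:
    """f_s = mean over input replicates of (var reads / ref reads).

    Replicates with zero reference reads are dropped from the mean;
    a SNP with no usable replicate is flagged uncomputable (NaN factor)
    rather than aborting the experiment.
    """
    input_rows = sheet.input_samples()
    if run is not None:
        input_rows = [r for r in input_rows if r.run == run]
    if not input_rows:
        raise NoInputSamples(
            "no input-plasmid samples" + (f" for run {run!r}" if run else "")
        )
    input_ids = [r.sample_id for r in input_rows]
    snp_ids = sorted({rid.rsplit("_", 1)[0] for rid in counts.index})
    factor, n_used, uncomputable = {}, {}, set()
    for snp in snp_ids:
        ref = counts.loc[f"{snp}_REF", input_ids].to_numpy(dtype=float)
        var = counts.loc[f"{snp}_VAR", input_ids].to_numpy(dtype=float)
        usable = ref > 0
        n_used[snp] = int(usable.sum())
        if not usable.any():
            factor[snp] = float("nan")
            uncomputable.add(snp)
        else:
            factor[snp] = float(np.mean(var[usable] / ref[usable]))
    return CorrectionFactors(factor=factor, n_used=n_used, uncomputable=uncomputable)


def apply_correction(
    table: SnpCountTable, factors: CorrectionFactors, mode: str = MODE_DIVIDE
) -> SnpCountTable:
    """Apply the plasmid-input correction to one SNP table.

    ``divide``: variant counts become raw / f (non-integer working
    counts). ``offset``: counts untouched, variant observations get a
    model offset of +ln f, so the structural predictor explains y / f —
    the exact GLM equivalent of dividing. The two agree in expectation.
    """
    f = factors[table.snp_id]
    is_var = table.genotype == 1
    if mode == MODE_DIVIDE:
        counts = table.counts.copy()
        counts[is_var] = counts[is_var] / f
        return replace(table, counts=counts, corrected=True)
    if mode == MODE_OFFSET:
        offset = table.offset.copy()
        offset[is_var] += math.log(f)
        return replace(table, offset=offset, corrected=True)
    raise ValueError(f"unknown correction mode {mode!r}")


# --------------------------------------------------------------------------
# NB GLM core
# --------------------------------------------------------------------------
def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Residual deviance; continuous in y, Poisson limit at phi=0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi < _PHI_MIN:
        dev = 2.0 * np.sum(term1 - (y - mu))
    else:
        r = 1.0 / phi
        dev = 2.0 * np.sum(term1 - (y + r) * np.log((y + r) / (mu + r)))
    return float(max(dev, 0.0))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood, gamma-extended to real-valued y."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    if phi < _PHI_MIN:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + y * np.log(mu / (mu + r))
            + r * np.log(r / (mu + r))
        )
    )


def _fit_irls(
    y: np.ndarray,
    X: np.ndarray,
    phi: float,
    offset: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Log-link NB regression via iteratively reweighted least squares.

    Returns (beta, mu, deviance, converged). Convergence is a relative
    deviance change below *tol*.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.1 + 0.1
    eta = np.log(mu) - offset
    dev = _nb_deviance(y, mu, phi)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)  # = mu^2 / V(mu)
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)
        eta = X @ beta
        eta = np.clip(eta + offset, -30.0, 30.0) - offset  # guard overflow
        mu = np.exp(eta + offset)
        new_dev = _nb_deviance(y, mu, phi)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    return beta, mu, dev, converged


def nb_glm_lrt(table: SnpCountTable, dispersion: float) -> GlmResult:
    """Fit the full and genotype-free models; LRT on the genotype term.

    If either allele's counts are all zero the coefficient diverges; a
    documented continuity rule adds 0.5 to every count of the SNP and
    refits, with the result flagged ``zero_allele``.
    """
    y = table.counts
    zero_allele = (
        y[table.genotype == 1].sum() == 0 or y[table.genotype == 0].sum() == 0
    )
    if zero_allele:
        y = y + 0.5
    X_full = table.design(with_genotype=True)
    X_red = table.design(with_genotype=False)
    beta, _, dev_full, conv_full = _fit_irls(y, X_full, dispersion, table.offset)
    _, _, dev_red, conv_red = _fit_irls(y, X_red, dispersion, table.offset)
    stat = max(dev_red - dev_full, 0.0)
    p = float(chi2.sf(stat, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GlmResult(
        snp_id=table.snp_id,
        cell_line=table.cell_line,
        log2fc=float(beta[-1] / math.log(2.0)),
        lrt_stat=stat,
        p_value=p,
        converged=conv_full and conv_red,
        zero_allele=bool(zero_allele),
    )


# --------------------------------------------------------------------------
# dispersion estimation
# --------------------------------------------------------------------------
def _profile_loglik(tables: list[SnpCountTable], phi: float) -> float:
    """Adjusted profile log-likelihood of phi, means profiled out.

    The plain profile likelihood is badly biased here: each SNP's
    design spends 6 of 10 degrees of freedom on mean parameters, which
    drags the dispersion MLE toward zero. The standard modified-profile
    (Cox-Reid-type) adjustment, -0.5 log det(X'WX), restores the lost
    degrees of freedom.
    """
    total = 0.0
    for t in tables:
        y = t.counts
        if y.sum() == 0:
            continue
        X = t.design(with_genotype=True)
        _, mu, _, _ = _fit_irls(y, X, phi, t.offset, tol=1e-6, max_iter=50)
        w = mu / (1.0 + phi * mu)
        _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
        total += _nb_loglik(y, mu, phi) - 0.5 * logdet
    return total


def _mle_phi(tables: list[SnpCountTable]) -> float:
    res = minimize_scalar(
        lambda lg: -_profile_loglik(tables, 10.0 ** lg),
        bounds=(math.log10(_PHI_MIN), math.log10(_PHI_MAX)),
        method="bounded",
        options={"xatol": 2e-2},
    )
    return float(10.0 ** res.x)


def estimate_dispersion(
    tables: list[SnpCountTable],
    n_prior: float = 10.0,
    tagwise: bool = True,
) -> DispersionEstimate:
    """Common + shrunk per-SNP dispersion for one cell line's tables.

    The common dispersion maximizes the profile log-likelihood summed
    over SNPs (replicate+genotype means refit at each candidate phi).
    Per-SNP maximum-likelihood values are shrunk toward the common value
    with weight ``w = n_prior / (n_prior + n_replicates)`` on the common
    component.
    """
    tables = [t for t in tables if len(t.counts)]
    if not tables or all(t.counts.sum() == 0 for t in tables):
        raise DegenerateData("all counts are zero; dispersion is undefined")
    n_reps = max(t.n_replicates for t in tables)
    if n_reps < 2:
        raise TooFewReplicates("dispersion estimation needs >= 2 replicates")
    phi_common = _mle_phi(tables)
    if phi_common <= _PHI_MIN * 10:
        phi_common = 0.0
    w = n_prior / (n_prior + n_reps)
    phi_snp = {}
    if tagwise:
        for t in tables:
            if t.counts.sum() == 0:
                phi_snp[t.snp_id] = phi_common
                continue
            phi_s = _mle_phi([t])
            if phi_s <= _PHI_MIN * 10:
                phi_s = 0.0
            phi_snp[t.snp_id] = w * phi_common + (1.0 - w) * phi_s
    return DispersionEstimate(
        phi_common=phi_common,
        phi_snp=phi_snp,
        shrinkage_weight=w,
        n_prior=n_prior,
    )


# --------------------------------------------------------------------------
# multiple testing, effect coding, summaries
# --------------------------------------------------------------------------
def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DegenerateData("bh_adjust: empty p-value collection")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def percent_change(log2fc: float) -> float:
    """(2^log2fc - 1) * 100: percent change of variant vs reference."""
    return (2.0 ** log2fc - 1.0) * 100.0


def categorize(percent: float) -> str:
    """Signed magnitude code: 0, -/+, --/++, ---/+++ at 5/10/15% bands."""
    mag = abs(percent)
    if mag < 5.0:
        return "0"
    symbol = "-" if percent < 0 else "+"
    if mag < 10.0:
        return symbol
    if mag < 15.0:
        return symbol * 2
    return symbol * 3


def merge_runs(table_a: SnpCountTable, table_b: SnpCountTable) -> SnpCountTable:
    """Stack one SNP's observations from two runs for a joint refit.

    The run label becomes an additional covariate in the design; apply
    per-run correction factors to each table *before* merging.
    """
    if table_a.snp_id != table_b.snp_id:
        raise PanelMismatch(
            f"cannot merge {table_a.snp_id!r} with {table_b.snp_id!r}",
            snp_ids=(table_a.snp_id, table_b.snp_id),
        )
    runs = set(table_a.run.tolist()) & set(table_b.run.tolist())
    if runs:
        raise PanelMismatch(f"runs overlap between tables: {sorted(runs)}")
    return SnpCountTable(
        snp_id=table_a.snp_id,
        cell_line=table_a.cell_line,
        counts=np.concatenate([table_a.counts, table_b.counts]),
        genotype=np.concatenate([table_a.genotype, table_b.genotype]),
        replicate=np.concatenate([table_a.replicate, table_b.replicate]),
        run=np.concatenate([table_a.run, table_b.run]),
        offset=np.concatenate([table_a.offset, table_b.offset]),
        corrected=table_a.corrected and table_b.corrected,
    )


@dataclass
class FunctionalSummary:
    per_cell_line: dict[str, int]
    union: int
    intersections: dict[tuple[str, ...], int]
    sets: dict[str, set[str]]


def call_functional(results: pd.DataFrame, fdr_threshold: float = 0.05) -> FunctionalSummary:
    """Per-cell-line functional SNP sets and their overlap structure.

    ``results`` needs columns snp_id, cell_line, fdr. Reports each cell
    line's count, the union ("functional in at least one cell line"),
    and the cardinality of every multi-cell-line intersection.
    """
    sets: dict[str, set[str]] = {}
    for cell_line, sub in results.groupby("cell_line", sort=False):
        sets[cell_line] = set(sub.loc[sub["fdr"] <= fdr_threshold, "snp_id"])
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    intersections = {}
    for k in range(2, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inter = set.intersection(*(sets[c] for c in combo))
            intersections[combo] = len(inter)
    return FunctionalSummary(
        per_cell_line={c: len(s) for c, s in sets.items()},
        union=len(union),
        intersections=intersections,
        sets=sets,
    )


# --------------------------------------------------------------------------
# experiment driver
# --------------------------------------------------------------------------
def snp_tables(
    counts: pd.DataFrame, sheet: SampleSheet, cell_line: str
) -> dict[str, SnpCountTable]:
    """Build per-SNP paired ref/var observation tables for a cell line."""
    cdna = sheet.cdna_samples(cell_line=cell_line)
    if not cdna:
        raise TooFewReplicates(f"no cdna samples for cell line {cell_line!r}")
    snp_ids = sorted({rid.rsplit("_", 1)[0] for rid in counts.index})
    tables = {}
    for snp in snp_ids:
        ref = counts.loc[f"{snp}_REF"]
        var = counts.loc[f"{snp}_VAR"]
        obs_counts, genotype, replicate, run = [], [], [], []
        for row in cdna:
            for geno, series in ((0, ref), (1, var)):
                obs_counts.append(float(series[row.sample_id]))
                genotype.append(geno)
                replicate.append(row.replicate)
                run.append(row.run)
        tables[snp] = SnpCountTable(
            snp_id=snp,
            cell_line=cell_line,
            counts=np.array(obs_counts),
            genotype=np.array(genotype),
            replicate=np.array(replicate),
            run=np.array(run, dtype=object),
        )
    return tables


def run_experiment(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    mode: str = MODE_DIVIDE,
    fdr_threshold: float = 0.05,
    bh_pool: str = "all",
    n_prior: float = 10.0,
    tagwise: bool = False,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full differential analysis of one experiment's count matrix.

    Steps: per-run input correction factors; per-SNP, per-cell-line NB
    GLM with replicate (+run) covariates and an LRT on genotype; BH FDR
    pooled across all (SNP x cell line) tests (``bh_pool="all"``, the
    default) or within each cell line (``"per-cell-line"``); percent
    change, category coding and the functional flag.

    By default every SNP is tested at the cell line's common
    dispersion: with 5 replicate pairs the per-SNP dispersion MLE has
    ~4 residual degrees of freedom and is so noisy (often exactly 0)
    that even shrunk tagwise values visibly inflate the null tail.
    ``tagwise=True`` switches to the shrunk per-SNP estimates. Passing
    ``dispersion`` skips estimation entirely and uses that fixed value
    (useful for oracle comparisons at phi = 0).
    """
    runs = sorted({r.run for r in sheet.cdna_samples()})
    # per-run factors where a run sequenced its own input pool; pooled otherwise
    pooled_factors = input_correction_factors(counts, sheet)
    factors_by_run = {}
    for run in runs:
        try:
            factors_by_run[run] = input_correction_factors(counts, sheet, run=run)
        except NoInputSamples:
            factors_by_run[run] = pooled_factors

    records = []
    for cell_line in sheet.cell_lines:
        merged: dict[str, SnpCountTable] = {}
        for run in runs:
            run_sheet = SampleSheet(
                [r for r in sheet.rows if r.role == "input" or r.run == run]
            )
            if not run_sheet.cdna_samples(cell_line=cell_line):
                continue
            tables = snp_tables(counts, run_sheet, cell_line)
            for snp, t in tables.items():
                try:
                    t = apply_correction(t, factors_by_run[run], mode=mode)
                except MissingFactor:
                    continue  # uncomputable factor: SNP dropped, reported absent
                merged[snp] = t if snp not in merged else merge_runs(merged[snp], t)
        if not merged:
            continue
        table_list = list(merged.values())
        if dispersion is None:
            disp = estimate_dispersion(table_list, n_prior=n_prior, tagwise=tagwise)
            phi = disp.for_snp
        else:
            phi = lambda snp: dispersion  # noqa: E731
        for snp, t in merged.items():
            res = nb_glm_lrt(t, phi(snp))
            records.append(
                {
                    "snp_id": snp,
                    "cell_line": cell_line,
                    "log2fc": res.log2fc,
                    "p_value": res.p_value,
                    "converged": res.converged,
                    "zero_allele": res.zero_allele,
                }
            )
    results = pd.DataFrame(records)
    if results.empty:
        raise DegenerateData("no testable (snp, cell line) pairs")
    if bh_pool == "all":
        results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    elif bh_pool == "per-cell-line":
        results["fdr"] = np.nan
        for cl in results["cell_line"].unique():
            mask = results["cell_line"] == cl
            results.loc[mask, "fdr"] = bh_adjust(results.loc[mask, "p_value"].to_numpy())
    else:
        raise ValueError(f"unknown bh_pool {bh_pool!r}")
    results["percent_change"] = results["log2fc"].map(percent_change)
    results["category"] = results["percent_change"].map(categorize)
    results["functional"] = results["fdr"] <= fdr_threshold
    cols = [
        "snp_id", "cell_line", "log2fc", "percent_change",
        "p_value", "fdr", "functional", "category", "converged", "zero_allele",
    ]
    return results[cols].reset_index(drop=True)
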