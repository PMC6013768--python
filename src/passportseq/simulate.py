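"""Synthetic data with known truth, at count level and at read level.

The generator mirrors the structure of a pooled dual-barcode reporter
experiment: 100 SNPs (200 allele-paired fragments), 4 sequenced
input-plasmid replicates, and 5 biological replicates in each of 3 cell
lines — 19 barcoded samples in all. Counts are negative-binomially
dispersed around per-sample means, with a per-SNP input-pool imbalance
factor and per-(SNP, cell line) allele effects planted as true log2
fold-changes. Reads are emitted as ``fwd_barcode + fragment +
revcomp(rev_barcode)`` amplicons with independent per-base substitution
errors and random orientation.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import ConfigError, TooManySamples
from .panel_design import FLANK3_LEN, FLANK5_LEN, MirSNP, ReferenceLibrary
from .readproc import BARCODE_LEN, CDNA, INPUT, BarcodePair, SampleRow, SampleSheet, SequencedRead

_BASES = np.array(list("ACGT"))

DEFAULT_CELL_LINES = ("HEK293", "HepG2", "HeLa")


@dataclass
class SimulationConfig:
    """Study-design parameters for count-level simulation.

    Defaults reproduce the assay's design: 100 SNPs, 4 input
    replicates, 5 biological replicates in each of 3 cell lines, a mean
    of 1,000 reads per fragment per sample, NB dispersion 0.05,
    log-normal input-pool imbalance and replicate depth variation, and
    cell-line-specific effects drawn for half the SNPs.
    """

    n_snps: int = 100
    cell_lines: Sequence[str] = DEFAULT_CELL_LINES
    n_bio_replicates: int = 5
    n_input_replicates: int = 4
    mean_reads: float = 1000.0
    dispersion: float = 0.05
    #: dispersion of the input-plasmid replicates. These are technical
    #: re-measurements of one fixed pool (library prep + sequencing of
    #: the same plasmid prep), so their counting noise is Poisson by
    #: default; biological dispersion applies only to cDNA samples.
    input_dispersion: float = 0.0
    frac_nonnull: float = 0.5
    #: sd of Normal(0, sd) effect draws; ignored when effect_log2fc is set
    effect_log2fc_sd: float = 0.5
    #: fixed |log2fc| with random sign, overriding the Normal draw
    effect_log2fc: float | None = None
    #: sd of log-normal input imbalance: log(f) ~ Normal(0, sd)
    imbalance_log_sd: float = 0.25
    #: fixed imbalance factor for every SNP, overriding the draw
    imbalance_factor: float | None = None
    #: sd of log-normal replicate depth variation around mean_reads
    depth_log_sd: float = 0.3
    error_rate: float = 0.0
    run: str = "run1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.n_bio_replicates < 1 or self.n_input_replicates < 1:
            raise ConfigError("replicate counts must be >= 1")
        if not self.cell_lines:
            raise ConfigError("need at least one cell line")
        if self.mean_reads <= 0:
            raise ConfigError("mean_reads must be positive")
        if self.dispersion < 0 or self.input_dispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        if not 0.0 <= self.frac_nonnull <= 1.0:
            raise ConfigError("frac_nonnull must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    factor: dict[str, float]  # per snp_id: true input imbalance f
    log2fc: dict[tuple[str, str], float]  # per (snp_id, cell_line)
    null: dict[tuple[str, str], bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": snp,
                "cell_line": cl,
                "true_f": self.factor[snp],
                "true_log2fc": fc,
                "null": self.null[(snp, cl)],
            }
            for (snp, cl), fc in self.log2fc.items()
        ]
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_panel(
    n_snps: int,
    seed: int,
    embed_mirna=None,
    embed_fraction: float = 0.0,
    flank5_len: int = FLANK5_LEN,
    flank3_len: int = FLANK3_LEN,
) -> list[MirSNP]:
    """Random designable SNVs, optionally with planted seed sites.

    When ``embed_mirna`` is given, a fraction of SNPs carry that
    miRNA's 8mer site complement overlapping the variant position with
    the reference allele completing the site (so the variant destroys
    it). Construction is verified with the seed scanner and resampled
    on the rare accidental collision.
    """
    from .seed_scan import UNCHANGED, classify_mirsnp

    rng = np.random.default_rng(seed)
    pattern = embed_mirna.site_patterns()["8mer"] if embed_mirna is not None else None
    snps: list[MirSNP] = []
    seen_windows: set[str] = set()
    for i in range(n_snps):
        embed = pattern is not None and rng.random() < embed_fraction
        for _attempt in range(50):
            flank5 = _random_seq(rng, flank5_len)
            flank3 = _random_seq(rng, flank3_len)
            if embed:
                # place the 8-nt site across the variant base at offset j
                j = int(rng.integers(0, len(pattern)))
                ref = pattern[j]
                before, after = pattern[:j], pattern[j + 1 :]
                if before:
                    flank5 = flank5[: -len(before)] + before
                if after:
                    flank3 = after + flank3[len(after) :]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                ref, alt = str(ref), str(alt)
            snp = MirSNP(
                snp_id=f"snp{i + 1:04d}",
                ref_allele=ref,
                alt_allele=alt,
                flank5=flank5,
                flank3=flank3,
            )
            key = flank5[-FLANK5_LEN:] + ref + flank3[:FLANK3_LEN]
            if key in seen_windows:
                continue
            if embed:
                hits = classify_mirsnp(snp, [embed_mirna])
                if not hits or all(h.status == UNCHANGED for h in hits):
                    continue
            seen_windows.add(key)
            snps.append(snp)
            break
        else:  # pragma: no cover - 50 resamples virtually never exhaust
            raise ConfigError(f"could not construct SNP {i + 1}")
    return snps


def make_barcode_plan(
    n_input_replicates: int,
    cell_lines: Sequence[str],
    n_bio_replicates: int,
    seed: int,
    run: str = "run1",
) -> SampleSheet:
    """Sample sheet with unique dual 6-nt barcodes for every sample.

    All forward and reverse barcodes are mutually at Hamming distance
    >= 2 (across the pooled set, so no read orientation can alias one
    sample's pair onto another's).
    """
    n_samples = n_input_replicates + len(cell_lines) * n_bio_replicates
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < 2 * n_samples:
        attempts += 1
        if attempts > 200_000:
            raise TooManySamples(
                f"cannot place {n_samples} samples with distance-2 barcodes"
            )
        cand = _random_seq(rng, BARCODE_LEN)
        if all(sum(a != b for a, b in zip(cand, bc)) >= 2 for bc in barcodes):
            barcodes.append(cand)
    fwd, rev = barcodes[:n_samples], barcodes[n_samples:]
    rows = []
    k = 0
    for i in range(n_input_replicates):
        rows.append(
            SampleRow(
                sample_id=f"input_{i + 1}",
                role=INPUT,
                cell_line="-",
                replicate=i + 1,
                run=run,
                barcode=BarcodePair(fwd[k], rev[k]),
            )
        )
        k += 1
    for cell_line in cell_lines:
        for r in range(n_bio_replicates):
            rows.append(
                SampleRow(
                    sample_id=f"{cell_line}_rep{r + 1}",
                    role=CDNA,
                    cell_line=cell_line,
                    replicate=r + 1,
                    run=run,
                    barcode=BarcodePair(fwd[k], rev[k]),
                )
            )
            k += 1
    return SampleSheet(rows)


def _nb_draw(rng: np.random.Generator, mean, phi: float):
    """NB(mean, dispersion phi) draws; Poisson at phi = 0."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
    snp_ids: Sequence[str] | None = None,
    sheet: SampleSheet | None = None,
) -> tuple[pd.DataFrame, SampleSheet, SimTruth]:
    """Simulate the fragments x samples count matrix plus its truth.

    Input samples draw ref ~ NB(mu0, phi_in) and var ~ NB(mu0 * f,
    phi_in) with the technical input dispersion (Poisson by default);
    cDNA samples draw ref ~ NB(mu_rep, phi) and
    var ~ NB(mu_rep * f * 2^log2fc, phi) with the biological
    dispersion, mu_rep log-normally varied per sample around the
    configured mean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1:04d}" for i in range(config.n_snps)]
    elif len(snp_ids) != config.n_snps:
        raise ConfigError("snp_ids length != n_snps")
    if sheet is None:
        sheet = make_barcode_plan(
            config.n_input_replicates,
            config.cell_lines,
            config.n_bio_replicates,
            seed=config.seed + 1,
            run=config.run,
        )

    if config.imbalance_factor is not None:
        f = np.full(config.n_snps, float(config.imbalance_factor))
    else:
        f = np.exp(rng.normal(0.0, config.imbalance_log_sd, size=config.n_snps))
    nonnull = rng.random(config.n_snps) < config.frac_nonnull
    truth = SimTruth(factor={}, log2fc={}, null={})
    effects = np.zeros((config.n_snps, len(config.cell_lines)))
    for j, cl in enumerate(config.cell_lines):
        if config.effect_log2fc is not None:
            drawn = config.effect_log2fc * rng.choice([-1.0, 1.0], size=config.n_snps)
        else:
            drawn = rng.normal(0.0, config.effect_log2fc_sd, size=config.n_snps)
        effects[:, j] = np.where(nonnull, drawn, 0.0)
    for i, snp in enumerate(snp_ids):
        truth.factor[snp] = float(f[i])
        for j, cl in enumerate(config.cell_lines):
            truth.log2fc[(snp, cl)] = float(effects[i, j])
            truth.null[(snp, cl)] = not bool(nonnull[i])

    index = []
    for snp in snp_ids:
        index.extend([f"{snp}_REF", f"{snp}_VAR"])
    mat = np.zeros((2 * config.n_snps, len(sheet)), dtype=np.int64)
    cl_index = {cl: j for j, cl in enumerate(config.cell_lines)}
    for col, row in enumerate(sheet):
        if row.role == INPUT:
            mu_ref = np.full(config.n_snps, config.mean_reads)
            mu_var = mu_ref * f
            mat[0::2, col] = _nb_draw(rng, mu_ref, config.input_dispersion)
            mat[1::2, col] = _nb_draw(rng, mu_var, config.input_dispersion)
            continue
        else:
            mu_rep = config.mean_reads * np.exp(rng.normal(0.0, config.depth_log_sd))
            mu_ref = np.full(config.n_snps, mu_rep)
            mu_var = mu_rep * f * 2.0 ** effects[:, cl_index[row.cell_line]]
        mat[0::2, col] = _nb_draw(rng, mu_ref, config.dispersion)
        mat[1::2, col] = _nb_draw(rng, mu_var, config.dispersion)
    counts = pd.DataFrame(mat, index=index, columns=sheet.sample_ids)
    return counts, sheet, truth


def simulate_reads(
    counts: pd.DataFrame,
    library: ReferenceLibrary,
    sheet: SampleSheet,
    error_rate: float = 0.0,
    seed: int = 0,
    flip_prob: float = 0.5,
) -> Iterator[SequencedRead]:
    """Yield amplicon reads realizing a count matrix.

    Each count unit becomes one read ``fwd_bc + fragment +
    revcomp(rev_bc)`` with i.i.d. per-base substitutions at
    ``error_rate`` and reverse-complement orientation with probability
    ``flip_prob``.
    """
    rng = np.random.default_rng(seed)
    bodies = {f.fragment_id: f.fragment for f in library}
    barcode = {r.sample_id: r.barcode for r in sheet}
    n = 0
    for sample_id in counts.columns:
        bc = barcode[sample_id]
        prefix, suffix = bc.fwd, revcomp(bc.rev)
        for fragment_id in counts.index:
            body = bodies[fragment_id]
            template = prefix + body + suffix
            for _ in range(int(counts.loc[fragment_id, sample_id])):
                n += 1
                bases = template
                if error_rate > 0:
                    arr = np.frombuffer(bases.encode(), dtype="S1").copy()
                    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                    for pos in hits:
                        current = arr[pos].decode()
                        arr[pos] = rng.choice(
                            [b for b in "ACGT" if b != current]
                        ).encode()
                    bases = arr.tobytes().decode()
                if rng.random() < flip_prob:
                    bases = revcomp(bases)
                yield SequencedRead(
                    read_id=f"sim_{n}", bases=bases, qualities="I" * len(bases)
                )
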