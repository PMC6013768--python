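# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `passportseq`. The package supports pooled,
allele-resolved miRNA-binding-site reporter assays: a panel of 3' UTR
SNPs is synthesized as paired reference/variant reporter fragments,
transfected as a pool, and read out by amplicon sequencing of dual-
barcoded libraries; the analysis asks, per SNP and cell line, whether
the variant allele's reporter mRNA abundance differs from the
reference allele's.

## Panel design

Each biallelic SNV is rendered as two 32-nt test windows: the 22 bases
immediately 5' of the variant, the allele base, and the 9 bases
immediately 3', so the allele always sits at window position 23
(1-based). Constant universal primer arms (5' `GTAATTCTAGGAGCTC`, 3'
`CGTTCTAGAGTCGGG`) wrap each window into a 63-nt synthesis fragment.
Fragment ids follow `<snp_id>_REF` / `<snp_id>_VAR`; every downstream
join keys on this convention.

Design decisions made where the procedure was open:

- Flanks are taken as given on the annotated transcript (3' UTR)
  strand; the designer never reverse-complements. The assay probes the
  mRNA-sense sequence, and strand resolution from a genome belongs to
  the VCF import, not the designer. For genes on the minus strand the
  caller must supply transcript-strand flanks; this is a documented
  assumption.
- Indels and MNVs are rejected rather than designed with shifted
  windows: silently supporting them would change the window arithmetic
  and the exactly-one-mismatch guarantee between allele pairs.
- Soft-masked (lowercase) bases are uppercased; IUPAC ambiguity codes
  are errors, because a synthesized oligo needs a concrete sequence.
- `screen_fragment` warns (never fails) on SacI/BmtI sites inside the
  window (the vector is linearized with those enzymes), homopolymer
  runs >= 8 nt, and window GC outside [0.10, 0.90].

## Seed-site scanning

mirSNP candidacy is decided by canonical seed matching only. A miRNA's
seed is positions 2-8 of the mature sequence; the mRNA site patterns
are the Watson-Crick reverse complements: `8mer` (revcomp 2-8 plus a
literal A opposite position 1), `7mer-m8` (revcomp 2-8), `7mer-A1`
(revcomp 2-7 plus A), `6mer` (revcomp 2-7). GU wobble and 3'-
supplementary pairing are deliberately out of scope; no context or
conservation scoring is attempted — presence/absence of a canonical
site is the decision variable.

Longer site types mask shorter ones whose interval they contain (an
8mer is not additionally a 7mer or 6mer); between the equal-length
7mers, `7mer-m8` takes precedence. Classification scans a window of 8
bases on either side of each allele (`flank_width = 8`, matching the
selection procedure the assay was designed around; the 22/9 assay
window is deliberately not reused for prediction) and compares only
sites whose span covers the variant base — a SNP cannot alter a site
it does not touch. A site present only with the reference allele is
`site_lost`, only with the alternate `site_gained`, present in both
with different type or position `site_type_changed`.

## Read processing

Amplicon reads have the structure `fwd_bc(6) + fragment(63) +
revcomp(rev_bc)(6)`. Demultiplexing requires a perfect match of both
barcodes, testing the read and then its reverse complement (single-end
amplicon sequencing reads either strand; assigned reads are
canonicalized to forward orientation and trimmed). There is no
error-correcting barcode recovery, by design. The generated barcode
sets keep every forward and reverse barcode at pairwise Hamming
distance >= 2 across the pooled set, which also excludes
cross-orientation aliasing of one sample's pair onto another's.

Fragment assignment is deterministic rather than aligner-based: an
exact-match fast path (read body, or body with intact arms stripped),
then a global edit-distance comparison (edlib, Needleman-Wunsch)
against every fragment body. A read is assigned iff its best distance
is <= `max_edits` (default 2) and beats the runner-up by >=
`min_margin` (default 1). Because REF/VAR bodies differ at exactly one
base, the margin rule makes cross-allele mis-assignment by tie
impossible: a read with an error at the allele base itself is
equidistant from both alleles and is dropped as ambiguous. This plays
the role a mapping-quality filter plays in aligner-based pipelines and
is strictly conservative about allele identity. Reads are streamed;
only the count matrix and tallies are held in memory.

QC: library representation is the fraction of fragments with at least
`detection_min` (default 1) input-pool reads. Replicate agreement is
the squared Pearson correlation of per-fragment
`log2((count + 0.5) / (mean input count + 0.5))` vectors between
replicate pairs; the 0.5 pseudocount admits zeros. This normalization
is QC-only and never feeds the statistics.

## Differential testing

**Input correction.** The transfected pool is not perfectly
allele-balanced. Per SNP, the correction factor `f` is the mean over
sequenced input-plasmid replicates of (variant reads / reference
reads) — the mean of ratios, not the ratio of means. Replicates with
zero reference reads are dropped from the mean and reported; a SNP
with no usable replicate is flagged uncomputable and excluded from
testing. Correction is applied per sequencing run when a run has its
own input libraries. Two equivalent applications are offered:
`divide` (default), which divides variant counts by `f` and treats the
resulting non-integer working counts through the gamma-function
continuous extension of the NB likelihood; and `offset`, which leaves
counts intact and gives variant observations a model offset `+ln f` —
the exact GLM form of the same adjustment (the structural predictor
then explains `y / f`). The two agree on log2 fold-change to < 0.02 at
deep counts.

**Model.** Counts follow a negative binomial with variance
`mu + phi * mu^2`; a log-link GLM regresses each SNP's paired
observations on an intercept, replicate indicators, run indicators
(when runs are merged) and a genotype indicator. Because both alleles
of a SNP are amplified from the same well, the replicate indicator
absorbs per-well depth exactly and no between-sample normalization
(TMM or similar) is applied. Fitting is IRLS to a relative deviance
change < 1e-8 (max 100 iterations); log2fc is the genotype coefficient
divided by ln 2; the p-value is the likelihood-ratio statistic
(reduced minus full deviance) against chi-square(1). If either
allele's counts are all zero the coefficient diverges; a continuity
rule adds 0.5 to every count of that SNP, refits, and flags the
result.

**Dispersion.** A common dispersion per cell line maximizes the
adjusted profile log-likelihood summed over SNPs: means are refit at
each candidate `phi` and the modified-profile correction
`-0.5 log det(X'WX)` is applied. The correction matters here: each
SNP's design spends 6 of 10 degrees of freedom on mean parameters, and
the unadjusted profile MLE underestimates `phi` by roughly the
residual-df fraction (~60% at 5 replicates), which in turn inflates
every LRT statistic. Per-SNP maximum-likelihood dispersions are shrunk
toward the common value with weight `n_prior / (n_prior + n_reps)` on
the common component (`n_prior = 10`, so ~2/3 at 5 replicates).
Optimization is bounded Brent on log10(phi) in [1e-8, 5]; estimates
within 1e-7 of the boundary are reported as exactly 0 (Poisson).

The pipeline tests every SNP at the *common* dispersion by default.
With 5 replicate pairs the per-SNP MLE has ~4 residual degrees of
freedom and is frequently exactly 0; even after shrinkage, the
remaining 1/3 weight on that floor-prone estimate pulls many SNPs'
working dispersion well below truth and inflates the null tail of the
LRT severalfold at small p. Shrunk per-SNP values remain available
(`tagwise=True`) for settings with more replicates, where the MLE
carries real information.

**Multiple testing and calls.** p-values from all (SNP x cell line)
tests of an experiment are pooled through the Benjamini-Hochberg
step-up (`q_(i) = min_{j>=i} p_(j) m / j`, capped at 1); per-cell-line
pooling is available behind a flag. A SNP is functional in a cell
line when FDR <= 0.05 (inclusive). Effects are also reported as
percent change `(2^log2fc - 1) * 100` and coded by signed magnitude:
|pct| < 5 -> `0`; 5-10 -> `-`/`+`; 10-15 -> `--`/`++`; >= 15 ->
`---`/`+++`. Overlap summaries report per-cell-line counts, the union,
and every multi-set intersection cardinality.

**Merging runs.** Observations from two sequencing runs of the same
panel are stacked per SNP after per-run input correction, a run
indicator joins the covariates, and the model is refit. Runs with
distinct depths but a shared true effect tighten the estimate; a run
missing a SNP raises a panel mismatch naming it.

## Synthetic data

The generator mirrors the assay's design: 100 SNPs (200 fragments), 4
input replicates, 5 biological replicates in each of 3 cell lines — 19
dual-barcoded samples. Defaults, chosen once as realistic for this
class of experiment: mean 1,000 reads per fragment per sample;
biological dispersion `phi = 0.05` (BCV ~22%, typical of transfected
reporter replicates); input imbalance `f` log-normal with log-sd 0.25;
replicate depth log-normal with log-sd 0.3; half the SNPs non-null
with per-cell-line effects drawn Normal(0, 0.5) on the log2 scale (a
fixed |log2fc| with random sign is available for power studies).

Input-plasmid replicates are technical re-measurements of one fixed
pool (library prep and sequencing of the same plasmid prep), so their
counts are Poisson by default (`input_dispersion = 0`); the biological
dispersion applies only to cDNA samples. This distinction is load-
bearing: the correction factor is estimated from the input replicates,
and its sampling noise enters every genotype test as a per-SNP shift.
If input replicates carried the full biological dispersion, that noise
would inflate the genotype LRT by a depth-independent factor of ~2.25
(variance `2 phi / 4` added to a coefficient variance of `2 phi / 5`)
and no correction-then-test pipeline of this shape could be calibrated.
Modeling input libraries as technical replicates is both the realistic
reading of the design and the regime in which the test's nominal
calibration holds. `input_dispersion` is a config field, so the
pessimistic regime remains simulatable.

Read-level simulation emits each count unit as a dual-barcoded
amplicon with i.i.d. per-base substitution errors and random
orientation. Indel errors are not simulated (the assignment budget is
edit-distance based, and substitutions exercise every code path);
PCR-duplicate structure and per-cell-line miRNA expression profiles
are likewise not modeled — effects are planted directly as log2
fold-changes. Everything is deterministic given the seed.

What passing tests on these simulations do not show about real data:
no aligner artifacts, no flow-space/homopolymer error structure, no
PCR jackpotting in the input pool, and no uncertainty about which
miRNA drives an observed allele effect.

## Calibration and power, verified by simulation

The validation suite recomputes, from scratch: exact agreement of the
BH implementation with a brute-force step-up oracle; agreement of the
LRT at `phi = 0` with the exact conditional binomial test (|delta p|
<= 0.02 at counts >= 500, where conditioning on the per-table total
makes variant reads Binomial(total, 1/2) under the null); near-
uniformity of null p-values (KS distance ~0.02 at 12,000 pooled tests
across 20 simulated experiments of 200 SNPs x 3 cell lines); planted-
effect recovery (mean estimated log2fc within 0.05 of a planted 0.5);
and imbalance correction (pure `f = 2` imbalance with no effect
centers estimates at 0 corrected and at log2 f = 1 uncorrected).

One intrinsic limit is worth stating plainly: at `phi = 0.05` with 5
replicate pairs, the genotype contrast's variance is bounded below by
`2 phi / n_rep = 0.02` on the ln scale no matter how deep the
sequencing, so the power to detect |log2fc| = 0.5 at FDR 0.05 tops
out near 70% (noncentrality ~6). Detecting such effects with >= 90%
power requires either `phi <~ 0.025`, more biological replicates, or
larger effects; the validation suite measures and reports the
achieved power rather than assuming it.

## Numerical choices and degenerate inputs

- IRLS starts at `mu = y + 0.1 * mean(y) + 0.1`; the linear predictor
  is clipped to ±30 to guard overflow; singular weighted normal
  equations fall back to least squares.
- NB deviance and log-likelihood use the continuous (gamma-function)
  extension so divide-mode working counts are handled exactly;
  `phi < 1e-8` switches to the Poisson limit.
- LRT statistics are floored at 0 (the nested fit can exceed the full
  fit only by convergence noise); p-values are clamped to (0, 1].
- All-zero SNPs are degenerate for dispersion estimation and excluded;
  all-zero alleles trigger the +0.5 continuity rule and a flag.
- Ties in BH are handled by stable sorting; the step-up minimum makes
  the result order-independent.

## Known limitations

- Assignment tolerates at most `max_edits` substitutions/indels and
  will discard heavily erroneous reads rather than rescue them.
- The dispersion model is a single common value per cell line plus
  fixed-weight shrinkage; no trended (mean-dependent) dispersion.
- The correction factor is a point estimate; its (small, technical)
  sampling noise is not propagated into the test. With deeply
  sequenced input pools this is negligible; with shallow or highly
  overdispersed input libraries it would not be.
- Percent-change categories are reported for all SNPs, significant or
  not; the functional flag alone encodes significance.
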