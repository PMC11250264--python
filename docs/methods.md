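# Methods

## Inference model

The pipeline assigns each tumor a cell-of-origin (COO) by exploiting the
inverse relationship between regional somatic mutation density and the
chromatin accessibility of the founding cell type. Its feature space is a
set of fixed-width genomic windows; its per-tumor statistic is the vector of
clonal mutation counts over those windows, normalized by the tumor's own
mean; its candidate origins are per-cell-type pseudobulk accessibility
profiles over the same windows.

### Windows

Autosomes are tiled from coordinate 0 in non-overlapping windows of
`window_size` bases (default 1,000,000). A window is retained iff

- its mappable fraction — bases covered by the uniquely-mappable-region
  track divided by `window_size` — is **≥ 0.92** (the exclusion rule drops
  windows *below* 92%, so the boundary value is retained),
- it overlaps the telomere/centromere gap track by **zero** bases (any
  overlap of one base or more excludes it; the source protocol states
  "overlapping" without a threshold, so the strictest reading is used),
- it lies on an autosome, and
- it is full length (trailing partial windows are dropped so every density
  feature shares one length scale).

The mappability and gap filters are computed independently on the tiled
windows; their order does not matter. All internal coordinates are 0-based
half-open (BED convention); VCF positions are converted by `pos − 1` on
ingest, so a variant at 1-based position 1,000,000 falls in the first 1-Mb
window and 1,000,001 opens the second. Interval arithmetic is delegated to
pyranges (merge + intersect); tests check it against an independent per-base
bitmap oracle on scaled-down windows.

### Clonal filter

Per tumor, the genome-wide mean and standard deviation of variant allele
fraction are computed over all ingested variants, and variants with
`VAF ≥ mean − k·SD` are kept (default `k = 1`). Choices the protocol leaves
open: the **sample** SD (n−1 denominator) is used; the comparison is
inclusive; the threshold is floored at 0; with fewer than two variants the
filter is skipped with a warning (sample SD undefined). VAF is taken from
INFO/AF when present, else alt-AD/DP from the configured tumor sample;
multi-allelic records are split; only PASS/unfiltered records are read;
SNVs and indels are treated identically.

### Accessibility features

scATAC fragments are assigned to the window containing the fragment
midpoint, `floor((start+end)/2)` — one window per fragment, keeping counts
integer and avoiding double counting (the source protocol does not state
its rule). Counts are accumulated per (window, major class) after mapping
barcodes → cluster → class; six classes by default (stem, goblet, BEST4,
enterocyte, tuft, enteroendocrine), supplied as an explicit mapping table
rather than hard-coded names. Each class column is then equalized: scaled
to sum to `equalize_total` (default 10,000,000, interpreting "reads" as
fragments). Equalization is scale-invariant and rank-preserving per column.

### Origin call

For one tumor, normalized density `y` is regressed on the windows ×
cell-types matrix `X` by gradient-boosted regression trees (XGBoost,
squared error) with `eta = 0.3` and `max_depth = 6` — the library defaults
the source protocol cites — and `n_rounds = 50`. The round count is not
given by the protocol; the recovery experiments pass identically at 25 and
100 rounds, showing insensitivity. Row/column subsampling is disabled and
`nthread = 1` so a fixed seed gives a deterministic model. The predicted
origin is the argmax of per-feature importance (default **total gain**;
cover and frequency are exposed), importances normalized to sum 1, ties
broken by lexicographic cell-type name. A constant `y`, or a fit in which
no feature accrues importance, yields an abstention. The fit is in-sample
over all retained windows — the quantity of interest is the importance
ranking, not held-out prediction error — and no further window subsetting
(e.g. to differential windows) is applied before prediction.

A caveat found during validation: XGBoost's split-gain accumulation is
sensitive to float summation order, so permuting feature columns can perturb
the importance vector in the last bits (measured max ~3·10⁻³ after 50
rounds, under both `hist` and `exact` tree methods). The origin *call* is
stable under permutation; the test suite asserts exactly that, plus
importance agreement within 0.02.

### Cohort statistics

- **Differential windows**: per-window two-sided Wilcoxon rank-sum between
  the two cohorts on normalized density. Exact null when both groups have
  ≤ 10 observations and no ties; otherwise the normal approximation with
  tie and continuity corrections. Significance is raw `p < 0.01` by
  default — matching the protocol's unadjusted screening rule — with
  Benjamini–Hochberg adjusted p-values reported alongside.
- **TMB comparison**: the same rank-sum test on per-tumor clonal variant
  counts.
- **Origin contingency**: predictions are aggregated into a cohorts ×
  origins table (abstentions tracked as a separate column and excluded from
  the test by default). Fisher's exact p is computed by full enumeration of
  all tables with the observed margins (probability-ordered two-sided
  definition, with a 10⁻⁷ relative tolerance when comparing table
  probabilities) whenever the table is 2×2 or the total is ≤ 40; larger
  tables use a seeded Monte-Carlo estimate (default 100,000 draws from the
  fixed-margin null via Patefield sampling, add-one estimator, standard
  error reported). Tests pin the enumeration to an independent
  hypergeometric-tail oracle on 2×2 tables and require Monte-Carlo
  agreement within 3 SE.

All tests are two-sided (sidedness is not stated by the protocol).

## Generative model (synthetic data)

The protocol has no generative model; the simulator's inverse-exponential
Poisson coupling is this package's choice, as the minimal structure with a
tunable, monotone anti-correlation for the predictor to exploit.

- **Reference**: one synthetic autosome of `n_windows × window_size` bases.
  The mappability track covers each window at Uniform(0.95, 1.0) except a
  `round(lowmap_fraction · n_windows)`-sized random subset covered at
  Uniform(0.80, 0.91) — below the 0.92 threshold — so window filtering has
  exact ground truth. The gap track is empty by default; gap filtering is
  exercised with hand-built tracks in tests.
- **Accessibility**: per window, a shared log-normal baseline
  `exp(N(0, shared_sigma²))` times a cell-specific factor
  `exp(N(0, cell_sigma²))`, columns equalized to `equalize_total`.
  Defaults `shared_sigma = 0.7`, `cell_sigma = 0.9` give pairwise
  inter-type Pearson correlations ≈ 0.2–0.35: correlated enough to be
  colon-like (epithelial lineages share most open chromatin), low enough
  that origins are identifiable.
- **Tumors**: per-window counts `Poisson(λ_w)` with
  `λ_w ∝ exp(−β·z_w)`, `z_w` the true origin's accessibility z-scored
  across windows (standardizing makes β comparable across profiles), rates
  rescaled so `Σλ_w = total_mutations` (checked to 10⁻⁹ relative). Variant
  positions are uniform within their window. Clonal VAFs are
  `Beta(mean = purity/2, concentration = clonal_vaf_conc)`; a
  `subclonal_fraction` of variants instead draws from
  `Beta(mean = purity/4)` — a documented constant placed below any
  plausible clonal threshold. An infinite concentration degenerates to
  VAF exactly `purity/2`. Defaults `purity = 0.8`,
  `clonal_vaf_conc = 80`, `subclonal_fraction = 0.15` make the clonal
  filter retain ≈ 85% of variants, matching the retention reported for
  real MSS colorectal genomes.
- **Cohorts**: origins drawn per cohort from a mixture over the panel
  (iterated in panel order, so YAML dict ordering cannot change draws).
  The default study emulates the published cohort shape: 25 IBD-CRC
  (goblet 40%, BEST4 28%) and 257 sCRC (stem 52%, goblet 22%, BEST4 17%,
  enterocyte 2%). The fractions those studies leave unstated (32% of
  IBD-CRC, 7% of sCRC) are spread evenly over the remaining panel types.
- **Fragments**: scATAC-like fragment files are realized per cell type by
  multinomial allocation of `fragments_per_type` fragments (length 200 bp)
  over windows proportional to the type's profile, assigned round-robin to
  `cells_per_type` barcodes, one cluster per type.
- β is a calibration knob, not an estimate: no quantitative
  density–accessibility coupling strength is available for real colorectal
  tumors. β = 2 is the default "strong signal" condition; β = 0 is the
  null.

### What the simulator does *not* emulate

No nucleotide sequence, trinucleotide signatures, replication-timing or
expression covariates of mutation rate, copy-number alterations, read-level
noise, doublets, or batch structure in the scATAC data. Passing recovery
tests therefore show that the implementation correctly inverts its own
generative assumption (density anti-correlated with origin accessibility),
not that real tumors satisfy it — on real data the signal is weaker and
confounded, and accuracy claims do not transfer.

## Numerical and design choices

- Determinism: every stochastic stage draws from
  `numpy.random.default_rng([seed, stage_tag, ...])` streams; XGBoost runs
  single-threaded without subsampling. Two end-to-end runs with the same
  config are byte-identical (asserted in tests).
- The pipeline manifest hashes each stage's config and inputs (SHA-256);
  unchanged stages are skipped on rerun, and a changed stage invalidates
  everything downstream.
- Window ids are dense `0..n−1` over retained windows; per-tumor counts are
  conserved (retained variants = window counts + discarded).
- Degenerate inputs: all-zero mutation rows, all-zero accessibility
  classes, unknown chromosomes, zero-depth VCF records and empty window
  sets raise errors naming the offender; fewer than two variants and
  degenerate contingency tables warn and fall back to neutral results.

## Problem sizes

The validation suite runs cohorts of 60–282 tumors over 120–500 windows
with 4,000–10,000 expected mutations per tumor, and the acceptance script
uses the default study (282 tumors, 500 windows). These sizes are chosen so
the recovery, null-calibration and power experiments are well-powered while
a full run stays in the tens of seconds on a single core; all scale
linearly in tumors × windows.

## Known limitations

- The 92%-mappability threshold assumes the supplied track is a 36-mer
  uniqueness track; computing k-mer uniqueness from a genome is out of
  scope.
- Fragment "support" columns are ignored (fragments, not deduplicated
  reads, are counted).
- The exact enumeration of r×c tables is exponential in principle; it is
  gated to totals ≤ 40, beyond which the seeded Monte-Carlo path is used.
- Importance-based origin calling yields a single label; it does not
  quantify mixtures of origins or calibrated uncertainty.
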