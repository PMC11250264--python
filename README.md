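# coorigin

Cell-of-origin inference for colorectal tumors from whole-genome somatic
mutation density and single-cell chromatin accessibility.

## The problem

Somatic mutation rates along a cancer genome are shaped by the chromatin of
the cell the tumor arose from: regions that were accessible in the founding
cell are repaired more efficiently and accumulate fewer mutations. Matching
the regional mutation density of a tumor against chromatin accessibility
profiles of candidate normal cell types therefore identifies the tumor's
likely cell-of-origin. This package implements that inference for colorectal
cancer cohorts — for example sporadic CRC (sCRC) versus CRC arising in
inflammatory bowel disease (IBD-CRC) — against six colonic epithelial
lineages profiled by scATAC: stem, goblet, BEST4, enterocyte, tuft and
enteroendocrine cells.

## The method

1. **Windows** — autosomes are tiled into non-overlapping 1-Mb windows;
   windows with < 92% uniquely-mappable bases, any overlap with
   telomere/centromere gaps, or trailing partial length are excluded.
2. **Clonal filter** — per tumor, variant allele fractions (VAF) are
   summarized genome-wide and variants with VAF ≥ mean − 1·SD are kept,
   restricting the density signal to clonal mutations present in the
   founding clone.
3. **Mutation density** — clonal variants are counted per window and each
   tumor's counts are normalized by its own window mean.
4. **Accessibility features** — scATAC fragments are aggregated by major
   cell class (fragment midpoint → window) and each class is equalized to a
   common total of 10 million.
5. **Origin call** — for each tumor, normalized density *y* over windows is
   regressed on the cell-type accessibility matrix *X* with gradient-boosted
   trees (squared error, η = 0.3, depth 6), and the cell type with the
   largest total-gain feature importance is called as the origin.
6. **Cohort statistics** — differentially mutated windows between cohorts
   (two-sided Wilcoxon rank-sum, P < 0.01), a rank-sum comparison of clonal
   tumor mutational burden, and Fisher's exact test on the cohorts × origins
   contingency table (full enumeration for small tables, seeded Monte-Carlo
   sampling from the fixed-margin null otherwise).

A synthetic-data module generates complete ground-truth studies — genome
layout, mappability track, accessibility profiles, fragment files, per-tumor
VCFs with clonal/subclonal VAF mixtures — under a generative model in which
per-window mutation counts are Poisson with rate ∝ exp(−β·z_w), where z_w is
the true origin's standardized accessibility. This makes every stage of the
pipeline verifiable without any external data.

## Worked example

```python
import coorigin as co

cfg = co.SimConfig(
    n_windows=200, total_mutations=5000, seed=42,
    cohort_spec=(co.CohortSpec("IBD-CRC", 10, {"goblet": 0.6, "BEST4": 0.4}),
                 co.CohortSpec("sCRC", 15, {"stem": 0.8, "goblet": 0.2})))

layout, mapp, gaps = co.simulate_reference(cfg)
windows = co.build_windows(layout, mapp, gaps, co.WindowFilterConfig())
access = co.simulate_accessibility(cfg, windows)
tumors, labels, truths = co.simulate_cohort(cfg, windows, access)

results = [co.clonal_filter(ts) for ts in tumors]
matrix = co.build_mutation_matrix(results, windows)
preds = co.predict_cohort(co.normalize_rows(matrix), access.equalized,
                          co.CooModelConfig(seed=7))
report = co.evaluate_against_truth(preds, labels["true_origin"])
summary = co.origin_contingency(preds, labels["cohort"], seed=7)
```

This prints (via the obvious `print` calls):

```
windows retained: 180 of 200
mean clonal retention: 84.6%
origin recovery accuracy: 1.00
origin   BEST4  goblet  stem
cohort
IBD-CRC      4       6     0
sCRC         0       1    14
Fisher exact p = 3.365e-06 (enumeration)
```

180 of 200 windows survive the mappability filter (the generator renders 10%
sub-threshold); the clonal filter keeps ~85% of variants under the default
clonal/subclonal VAF mixture; every simulated tumor's origin is recovered;
and the goblet/BEST4-dominant cohort separates from the stem-dominant one in
the exact test.

The same pipeline runs from the shell:

```sh
coo sim --outdir study --seed 42
coo windows --sizes study/sizes.tsv --mappability study/mappability.bed \
    --gaps study/gaps.bed --out study/windows.bed
coo filter-count --vcf-dir study/vcf --windows study/windows.bed --out study/matrix.tsv
coo atac --fragments study/fragments.tsv --barcodes study/barcodes.tsv \
    --classes study/classes.tsv --windows study/windows.bed --out study/features.tsv
coo predict --matrix study/matrix.tsv --features study/features.tsv --out study/pred.tsv
coo evaluate --predictions study/pred.tsv --truth study/truth.tsv --out study/eval.json
```

or end-to-end from one YAML config with a reproducibility manifest:
`coo run --config run.yaml`.

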