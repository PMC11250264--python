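"""Synthetic cohorts with known cell-of-origin ground truth.

The generator produces every input the inference pipeline consumes — genome
layout, mappability and gap tracks, per-cell-type accessibility profiles,
scATAC-like fragment files, and per-tumor somatic variant sets — under a
generative model that encodes the premise the predictor exploits: somatic
mutation density is anti-correlated with the chromatin accessibility of the
tumor's founding cell type.

Model
-----
Accessibility per cell type is a shared log-normal baseline multiplied by a
cell-specific log-normal component, then equalized to a common per-type
total. For a tumor of true origin t, per-window clonal mutation counts are
Poisson with rate lambda_w proportional to exp(-beta * z_w), where z_w is
the origin's accessibility in window w standardized across windows (z-score
per cell type, so beta is comparable across profiles), rescaled so the rates
sum to the configured total mutation count. Clonal variant allele fractions
follow a Beta centered at purity/2; a configurable fraction of variants is
subclonal with a Beta centered at purity/4 — below any plausible clonal
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atac import AccessibilityMatrix, AtacConfig, equalize
from .variants import TumorVariantSet
from .windows import GenomeLayout, Chromosome, IntervalTrack, WindowSet

__all__ = [
    "CohortSpec",
    "SimConfig",
    "SyntheticTruth",
    "simulate_reference",
    "simulate_accessibility",
    "simulate_tumor",
    "simulate_cohort",
    "simulate_fragments",
    "write_vcf",
    "write_sim_outputs",
]

DEFAULT_CELL_TYPES = ("stem", "goblet", "BEST4", "enterocyte", "tuft", "enteroendocrine")

# Cohort origin mixtures emulating the published cohort composition:
# sporadic CRC dominated by stem-cell origins, IBD-associated CRC dominated
# by secretory lineages (goblet, BEST4). Fractions not pinned down for the
# remaining types are spread evenly over them.
SCRC_MIXTURE = {
    "stem": 0.52, "goblet": 0.22, "BEST4": 0.17, "enterocyte": 0.02,
    "tuft": 0.035, "enteroendocrine": 0.035,
}
IBD_MIXTURE = {
    "goblet": 0.40, "BEST4": 0.28, "stem": 0.08, "enterocyte": 0.08,
    "tuft": 0.08, "enteroendocrine": 0.08,
}

# internal seed-stream tags so stages draw from independent streams
_REF, _ACCESS, _TUMOR, _ORIGINS, _FRAGS = 11, 22, 33, 44, 55


@dataclass(frozen=True)
class CohortSpec:
    label: str
    n_tumors: int
    origin_mixture: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        total = sum(self.origin_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"origin mixture for {self.label!r} sums to {total}, not 1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    coupling_beta is the strength of the mutation-accessibility
    anti-correlation (0 = no signal). total_mutations is the expected
    clonal burden per tumor. clonal_vaf_conc is the Beta concentration of
    the clonal VAF distribution; at the default the clonal filter retains
    roughly 85% of a mixed clonal/subclonal variant set. shared_sigma and
    cell_sigma are the log-scale SDs of the shared and cell-specific
    accessibility components; the defaults give pairwise inter-type Pearson
    correlations of roughly 0.4.
    """

    n_windows: int = 500
    window_size: int = 1_000_000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    coupling_beta: float = 2.0
    total_mutations: float = 10_000.0
    purity: float = 0.8
    clonal_vaf_conc: float = 80.0
    subclonal_fraction: float = 0.15
    cohort_spec: tuple[CohortSpec, ...] = (
        CohortSpec("IBD-CRC", 25, IBD_MIXTURE),
        CohortSpec("sCRC", 257, SCRC_MIXTURE),
    )
    lowmap_fraction: float = 0.1
    shared_sigma: float = 0.7
    cell_sigma: float = 0.9
    equalize_total: float = 10_000_000.0
    fragments_per_type: int = 200_000
    cells_per_type: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        self.cohort_spec = tuple(
            spec if isinstance(spec, CohortSpec)
            else CohortSpec(spec["label"], int(spec["n_tumors"]), dict(spec["origin_mixture"]))
            for spec in self.cohort_spec
        )
        if self.n_windows < 1 or self.window_size < 1:
            raise ValueError("n_windows and window_size must be positive")
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        if self.coupling_beta < 0:
            raise ValueError("coupling_beta must be >= 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 <= self.subclonal_fraction < 1:
            raise ValueError("subclonal_fraction must be in [0, 1)")
        if not 0 <= self.lowmap_fraction <= 1:
            raise ValueError("lowmap_fraction must be in [0, 1]")
        unknown = [
            t for spec in self.cohort_spec for t in spec.origin_mixture
            if t not in self.cell_types
        ]
        if unknown:
            raise ValueError(f"mixture cell types not in panel: {unknown}")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated tumor."""

    tumor_id: str
    origin: str
    window_rates: np.ndarray  # expected clonal mutations per retained window
    clonal_flags: np.ndarray  # per-variant: True = clonal


def _rng(config: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *tags])


def simulate_reference(config: SimConfig) -> tuple[GenomeLayout, IntervalTrack, IntervalTrack]:
    """One synthetic autosome with a mappability track and an empty gap track.

    All windows are covered >= 92% by the mappability track except a
    round(lowmap_fraction * n_windows)-sized random subset covered below the
    threshold, so downstream window filtering has known ground truth.
    """
    if config.n_windows < 2:
        raise ValueError("need at least 2 windows")
    rng = _rng(config, _REF)
    W, size = config.n_windows, config.window_size
    layout = GenomeLayout([Chromosome("chr1", W * size, autosome=True)])

    n_low = int(round(config.lowmap_fraction * W))
    low = set(rng.choice(W, size=n_low, replace=False).tolist()) if n_low else set()
    intervals = []
    for w in range(W):
        if w in low:
            frac = rng.uniform(0.80, 0.91)
        else:
            frac = rng.uniform(0.95, 1.0)
        covered = int(round(frac * size))
        intervals.append(("chr1", w * size, w * size + covered))
    mappability = IntervalTrack.from_intervals(intervals)
    gaps = IntervalTrack()
    return layout, mappability, gaps


def simulate_accessibility(config: SimConfig, windows: WindowSet) -> AccessibilityMatrix:
    """Per-cell-type accessibility: shared x cell-specific log-normal, equalized."""
    if windows.n == 0:
        raise ValueError("empty window set")
    rng = _rng(config, _ACCESS)
    W, T = windows.n, len(config.cell_types)
    shared = np.exp(rng.normal(0.0, config.shared_sigma, size=W))
    specific = np.exp(rng.normal(0.0, config.cell_sigma, size=(W, T)))
    raw = pd.DataFrame(shared[:, None] * specific,
                       index=pd.RangeIndex(W, name="window"),
                       columns=list(config.cell_types))
    return equalize(raw, AtacConfig(equalize_total=config.equalize_total))


def origin_rates(config: SimConfig, access: AccessibilityMatrix, true_origin: str) -> np.ndarray:
    """Expected per-window clonal mutation counts for a given origin.

    lambda_w proportional to exp(-beta * z_w) with z the origin column
    standardized across windows; rescaled to sum to total_mutations.
    """
    if true_origin not in access.equalized.columns:
        raise ValueError(f"origin {true_origin!r} not in accessibility panel")
    col = access.equalized[true_origin].to_numpy(dtype=float)
    sd = col.std()
    z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
    lam = np.exp(-config.coupling_beta * z)
    return lam * (config.total_mutations / lam.sum())


_BASES = np.array(list("ACGT"))


def simulate_tumor(config: SimConfig, windows: WindowSet, access: AccessibilityMatrix,
                   true_origin: str, tumor_id: str = "tumor", cohort: str | None = None,
                   tumor_tag: int = 0) -> tuple[TumorVariantSet, SyntheticTruth]:
    """Draw one tumor's somatic variants given its true cell-of-origin.

    Per-window counts are Poisson(origin_rates); positions are uniform within
    their window; clonal VAFs ~ Beta(mean purity/2), subclonal VAFs ~
    Beta(mean purity/4), both at concentration clonal_vaf_conc.
    """
    rng = _rng(config, _TUMOR, tumor_tag)
    lam = origin_rates(config, access, true_origin)
    counts = rng.poisson(lam)
    n = int(counts.sum())

    win = windows.windows
    win_idx = np.repeat(np.arange(windows.n), counts)
    starts = win["Start"].to_numpy()[win_idx]
    chroms = win["Chromosome"].to_numpy()[win_idx]
    offsets = rng.integers(0, config.window_size, size=n)
    pos = starts + offsets + 1  # 1-based VCF positions

    clonal = rng.random(n) >= config.subclonal_fraction
    conc = config.clonal_vaf_conc
    vaf = np.empty(n)
    for flag, mean in ((True, config.purity / 2), (False, config.purity / 4)):
        mask = clonal == flag
        if mask.any():
            if np.isinf(conc):  # degenerate limit: VAF exactly at the center
                vaf[mask] = mean
            else:
                vaf[mask] = rng.beta(mean * conc, (1 - mean) * conc, size=int(mask.sum()))

    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    df = pd.DataFrame({
        "Chromosome": chroms,
        "Pos": pos.astype(np.int64),
        "Ref": _BASES[ref_i],
        "Alt": _BASES[alt_i],
        "VAF": vaf,
    })
    order = np.lexsort((df["Pos"].to_numpy(), df["Chromosome"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    truth = SyntheticTruth(tumor_id, true_origin, lam, clonal[order])
    return TumorVariantSet(tumor_id, df, cohort=cohort), truth


def simulate_cohort(config: SimConfig, windows: WindowSet | None = None,
                    access: AccessibilityMatrix | None = None,
                    ) -> tuple[list[TumorVariantSet], pd.DataFrame, list[SyntheticTruth]]:
    """Simulate every cohort in config.cohort_spec.

    Origins are sampled from each cohort's mixture. When windows/access are
    not supplied they are built from simulate_reference via the standard
    window filter. Returns (tumor variant sets, label table, truths).
    """
    if not config.cohort_spec:
        raise ValueError("cohort_spec is empty")
    if windows is None or access is None:
        from .windows import WindowFilterConfig, build_windows

        layout, mapp, gaps = simulate_reference(config)
        windows = build_windows(layout, mapp, gaps,
                                WindowFilterConfig(window_size=config.window_size))
        access = simulate_accessibility(config, windows)

    rng = _rng(config, _ORIGINS)
    tumors, truths, rows = [], [], []
    tag = 0
    for spec in config.cohort_spec:
        # canonical panel order so draws are independent of dict key order
        types = [t for t in config.cell_types if t in spec.origin_mixture]
        probs = np.array([spec.origin_mixture[t] for t in types])
        origins = rng.choice(types, size=spec.n_tumors, p=probs / probs.sum())
        for i, origin in enumerate(origins):
            tumor_id = f"{spec.label}_{i:03d}"
            ts, truth = simulate_tumor(config, windows, access, str(origin),
                                       tumor_id=tumor_id, cohort=spec.label, tumor_tag=tag)
            tumors.append(ts)
            truths.append(truth)
            rows.append((tumor_id, spec.label, str(origin)))
            tag += 1
    labels = pd.DataFrame(rows, columns=["tumor", "cohort", "true_origin"]).set_index("tumor")
    return tumors, labels, truths


def simulate_fragments(config: SimConfig, windows: WindowSet,
                       access: AccessibilityMatrix) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """scATAC-like fragment file realizing the accessibility profiles.

    Per cell type, fragments_per_type fragments are multinomially distributed
    over windows proportional to the type's profile and assigned round-robin
    to cells_per_type barcodes. Returns (fragments, barcode annotation,
    cluster-to-class table); each cell type is its own cluster.
    """
    rng = _rng(config, _FRAGS)
    win = windows.windows
    frag_rows = []
    bc_rows = []
    cls_rows = []
    frag_len = 200
    for t, ct in enumerate(access.cell_types):
        probs = access.equalized[ct].to_numpy(dtype=float)
        probs = probs / probs.sum()
        counts = rng.multinomial(config.fragments_per_type, probs)
        win_idx = np.repeat(np.arange(windows.n), counts)
        starts = (win["Start"].to_numpy()[win_idx]
                  + rng.integers(0, config.window_size - frag_len,
                                 size=len(win_idx)))
        chroms = win["Chromosome"].to_numpy()[win_idx]
        barcodes = [f"{ct}_cell{i % config.cells_per_type:03d}" for i in range(len(win_idx))]
        frag_rows.append(pd.DataFrame({
            "Chromosome": chroms, "Start": starts, "End": starts + frag_len,
            "Barcode": barcodes,
        }))
        cluster = f"cluster_{ct}"
        bc_rows.extend((f"{ct}_cell{i:03d}", cluster) for i in range(config.cells_per_type))
        cls_rows.append((cluster, ct))
    fragments = pd.concat(frag_rows, ignore_index=True)
    fragments = fragments.sort_values(["Chromosome", "Start", "End", "Barcode"],
                                      kind="mergesort").reset_index(drop=True)
    barcodes = pd.DataFrame(bc_rows, columns=["barcode", "cluster"])
    classes = pd.DataFrame(cls_rows, columns=["cluster", "class"])
    return fragments, barcodes, classes


# ------------------------------------------------------------------- writers


def write_vcf(ts: TumorVariantSet, layout: GenomeLayout, path) -> None:
    """Write a VCF v4.2 with INFO/AF and a single sample carrying AD and DP.

    Depths are synthesized at DP=100 with the alt depth rounded from the
    allele fraction; AF carries the exact value.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coorigin-sim\n")
        for c in layout.chromosomes:
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        dp = 100
        for row in ts.variants.itertuples(index=False):
            alt_depth = int(round(row.VAF * dp))
            fh.write(
                f"{row.Chromosome}\t{row.Pos}\t.\t{row.Ref}\t{row.Alt}\t.\tPASS\t"
                f"AF={row.VAF:.6f}\tAD:DP\t{dp - alt_depth},{alt_depth}:{dp}\n"
            )


def write_sim_outputs(config: SimConfig, outdir) -> dict:
    """Run the full generator and write every pipeline input under outdir.

    Emits chrom-sizes TSV, mappability/gap BEDs, fragments TSV, barcode and
    class annotation TSVs, one VCF per tumor, the cohort label TSV and the
    truth TSV. Returns a manifest of paths.
    """
    import os

    from .windows import WindowFilterConfig, build_windows

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(str(outdir), name)  # noqa: E731

    layout, mapp, gaps = simulate_reference(config)
    layout.to_tsv(j("sizes.tsv"))
    mapp.to_bed(j("mappability.bed"))
    gaps.to_bed(j("gaps.bed"))

    windows = build_windows(layout, mapp, gaps,
                            WindowFilterConfig(window_size=config.window_size))
    access = simulate_accessibility(config, windows)
    fragments, barcodes, classes = simulate_fragments(config, windows, access)
    fragments.to_csv(j("fragments.tsv"), sep="\t", header=False, index=False)
    barcodes.to_csv(j("barcodes.tsv"), sep="\t", header=False, index=False)
    classes.to_csv(j("classes.tsv"), sep="\t", header=False, index=False)

    tumors, labels, truths = simulate_cohort(config, windows, access)
    vcf_dir = j("vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for ts in tumors:
        write_vcf(ts, layout, os.path.join(vcf_dir, f"{ts.tumor_id}.vcf"))
    labels[["cohort"]].to_csv(j("cohorts.tsv"), sep="\t")
    labels[["true_origin"]].to_csv(j("truth.tsv"), sep="\t")

    return {
        "sizes": j("sizes.tsv"), "mappability": j("mappability.bed"),
        "gaps": j("gaps.bed"), "fragments": j("fragments.tsv"),
        "barcodes": j("barcodes.tsv"), "classes": j("classes.tsv"),
        "vcf_dir": vcf_dir, "cohorts": j("cohorts.tsv"), "truth": j("truth.tsv"),
    }
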