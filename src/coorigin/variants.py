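"""Somatic variant ingestion, clonality filtering and per-window counting.

High-VAF variants are clonal: present in the tumor's founding clone. The
clonal filter keeps variants whose allele fraction is at least the tumor's
genome-wide mean minus a multiple (default 1) of its standard deviation,
removing subclonal calls whose regional density would reflect later
evolution rather than the cell-of-origin's chromatin state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .windows import WindowSet

__all__ = [
    "TumorVariantSet",
    "ClonalFilterConfig",
    "ClonalFilterResult",
    "MutationMatrix",
    "read_somatic_vcf",
    "clonal_filter",
    "count_per_window",
    "build_mutation_matrix",
    "normalize_rows",
    "compute_tmb",
]

VARIANT_COLUMNS = ["Chromosome", "Pos", "Ref", "Alt", "VAF"]


@dataclass
class TumorVariantSet:
    """Per-tumor somatic variants with allele fractions.

    `variants` columns: Chromosome, Pos (1-based), Ref, Alt, VAF.
    """

    tumor_id: str
    variants: pd.DataFrame
    cohort: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def vafs(self) -> np.ndarray:
        return self.variants["VAF"].to_numpy(dtype=float)


@dataclass
class ClonalFilterConfig:
    """Threshold = mean(VAF) - sd_multiplier * SD(VAF), floored at 0."""

    sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")


@dataclass
class ClonalFilterResult:
    tumor_id: str
    mean_vaf: float
    sd_vaf: float
    threshold: float
    retained: pd.DataFrame
    n_input: int
    warning: str | None = None

    @property
    def retained_fraction(self) -> float:
        return len(self.retained) / self.n_input if self.n_input else float("nan")

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def read_somatic_vcf(path, tumor_id: str | None = None, sample: str | None = None,
                     cohort: str | None = None) -> TumorVariantSet:
    """Read a somatic VCF into a TumorVariantSet.

    One record per PASS (or unfiltered) ALT allele; multi-allelic sites are
    split. VAF comes from INFO/AF when present, otherwise from the sample's
    AD and DP (alt depth / total depth). In multi-sample VCFs `sample` picks
    the tumor column (default: first sample).
    """
    vcf = VCF(str(path))
    sample_idx = 0
    if sample is not None:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in VCF {path}")
        sample_idx = vcf.samples.index(sample)
    rows = []
    for rec in vcf:
        if rec.FILTER is not None:  # cyvcf2: None means PASS or '.'
            continue
        af = rec.INFO.get("AF")
        if af is not None and not isinstance(af, (tuple, list)):
            af = (af,)
        for alt_i, alt in enumerate(rec.ALT):
            if af is not None:
                vaf = float(af[alt_i]) if alt_i < len(af) else float(af[0])
            else:
                vaf = _vaf_from_ad_dp(rec, alt_i, sample_idx, path)
            rows.append((rec.CHROM, rec.POS, rec.REF, alt, vaf))
    vcf.close()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if tumor_id is None:
        tumor_id = _stem(path)
    return TumorVariantSet(tumor_id, df, cohort=cohort)


def _vaf_from_ad_dp(rec, alt_i: int, sample_idx: int, path) -> float:
    where = f"{rec.CHROM}:{rec.POS} {rec.REF}>{rec.ALT[alt_i]} in {path}"
    ad = rec.format("AD")
    if ad is None:
        raise ValueError(f"no AF and no AD: cannot derive VAF for {where}")
    alt_depth = float(ad[sample_idx][alt_i + 1])
    dp = rec.format("DP")
    depth = float(dp[sample_idx][0]) if dp is not None else float(ad[sample_idx].sum())
    if depth <= 0:
        raise ValueError(f"DP is zero: cannot derive VAF for {where}")
    return alt_depth / depth


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    for suffix in (".gz", ".vcf"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base


def clonal_filter(ts: TumorVariantSet, cfg: ClonalFilterConfig | None = None) -> ClonalFilterResult:
    """Keep variants with VAF >= mean - sd_multiplier * SD (sample SD, n-1).

    The threshold is floored at 0 and the comparison is inclusive, so
    boundary variants are kept. With fewer than two variants the sample SD
    is undefined: everything is kept and a warning is recorded.
    """
    cfg = cfg or ClonalFilterConfig()
    vafs = ts.vafs
    if len(vafs) < 2:
        warn = "fewer than 2 variants; clonal filter skipped"
        warnings.warn(f"{ts.tumor_id}: {warn}")
        mean = float(vafs.mean()) if len(vafs) else float("nan")
        return ClonalFilterResult(ts.tumor_id, mean, float("nan"), 0.0,
                                  ts.variants.copy(), len(vafs), warning=warn)
    mean = float(vafs.mean())
    sd = float(vafs.std(ddof=1))
    threshold = max(mean - cfg.sd_multiplier * sd, 0.0)
    retained = ts.variants[ts.variants["VAF"] >= threshold].reset_index(drop=True)
    return ClonalFilterResult(ts.tumor_id, mean, sd, threshold, retained, len(vafs))


def count_per_window(result: ClonalFilterResult, windows: WindowSet) -> tuple[np.ndarray, int]:
    """Assign each retained variant to its window and count.

    A variant at 1-based position p belongs to the retained window containing
    0-based coordinate p-1. Variants falling in dropped windows (or beyond the
    tiled region of a known chromosome) are counted as discarded; an unknown
    chromosome is an error.
    """
    counts = np.zeros(windows.n, dtype=np.int64)
    discarded = 0
    for chrom, grp in result.retained.groupby("Chromosome", sort=False):
        ids = windows.locate(str(chrom), grp["Pos"].to_numpy(dtype=np.int64) - 1)
        inside = ids >= 0
        discarded += int((~inside).sum())
        np.add.at(counts, ids[inside], 1)
    return counts, discarded


@dataclass
class MutationMatrix:
    """Tumors x retained-windows counts with a per-patient normalized view."""

    counts: pd.DataFrame  # index: tumor id; columns: window ids
    discarded: pd.Series = field(default_factory=lambda: pd.Series(dtype=np.int64))

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative mutation counts")
        self.counts.index.name = "tumor"

    @property
    def n_tumors(self) -> int:
        return len(self.counts)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "discarded", self.discarded.reindex(out.index).fillna(0).astype(int))
        out.to_csv(path, sep="\t", index_label="tumor")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="tumor")
        discarded = df.pop("discarded")
        df.columns = df.columns.astype(int)
        return cls(df, discarded)


def build_mutation_matrix(results: list[ClonalFilterResult], windows: WindowSet) -> MutationMatrix:
    rows, discarded = {}, {}
    for res in results:
        if res.tumor_id in rows:
            raise ValueError(f"duplicate tumor id {res.tumor_id!r}")
        counts, disc = count_per_window(res, windows)
        rows[res.tumor_id] = counts
        discarded[res.tumor_id] = disc
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=np.arange(windows.n))
    return MutationMatrix(counts, pd.Series(discarded, dtype=np.int64))


def normalize_rows(m: MutationMatrix) -> pd.DataFrame:
    """Divide each tumor's counts by its own mean over windows (row mean -> 1)."""
    arr = m.counts.to_numpy(dtype=float)
    means = arr.mean(axis=1)
    zero = means == 0
    if zero.any():
        bad = m.counts.index[zero].tolist()
        raise ValueError(f"no clonal variants in retained windows for tumors: {bad}")
    return pd.DataFrame(arr / means[:, None], index=m.counts.index, columns=m.counts.columns)


def compute_tmb(result: ClonalFilterResult) -> int:
    """Tumor mutational burden: clonal (post-filter) variants per tumor."""
    return result.n_retained
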