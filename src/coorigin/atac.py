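"""Pseudobulk chromatin accessibility per cell type over the window set.

Single-cell ATAC fragments are aggregated by major cell class (six classes
for human colon: stem, goblet, BEST4, enterocyte, tuft, enteroendocrine)
into window x class counts, then each class is rescaled to a common total
(10 million by default) so that classes with different cell numbers are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import WindowSet

__all__ = [
    "CellAnnotation",
    "AtacConfig",
    "AccessibilityMatrix",
    "read_fragments",
    "aggregate_fragments",
    "equalize",
]


@dataclass
class CellAnnotation:
    """barcode -> cluster -> major class mapping.

    Barcodes whose cluster has no class mapping are flagged as unmapped and
    their fragments discarded during aggregation.
    """

    barcode_to_cluster: pd.Series
    cluster_to_class: pd.Series

    def __post_init__(self) -> None:
        if len(self.barcode_to_cluster) == 0:
            raise ValueError("empty barcode annotation")
        self.barcode_to_class = self.barcode_to_cluster.map(self.cluster_to_class)

    @property
    def classes(self) -> list[str]:
        return sorted(self.cluster_to_class.unique())

    @property
    def unmapped_barcodes(self) -> list[str]:
        mask = self.barcode_to_class.isna()
        return self.barcode_to_class.index[mask].tolist()

    @classmethod
    def from_tsv(cls, barcode_path, class_path) -> "CellAnnotation":
        bc = pd.read_csv(barcode_path, sep="\t", header=None, names=["barcode", "cluster"])
        cl = pd.read_csv(class_path, sep="\t", header=None, names=["cluster", "class"])
        return cls(bc.set_index("barcode")["cluster"], cl.set_index("cluster")["class"])


@dataclass
class AtacConfig:
    equalize_total: float = 10_000_000.0
    assignment_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if self.equalize_total <= 0:
            raise ValueError("equalize_total must be positive")
        if self.assignment_rule != "midpoint":
            raise ValueError("only midpoint assignment is supported")


@dataclass
class AccessibilityMatrix:
    """Windows x cell-type accessibility, raw and equalized."""

    raw: pd.DataFrame  # index: window id; columns: class names
    equalized: pd.DataFrame
    equalize_total: float

    @property
    def cell_types(self) -> list[str]:
        return list(self.equalized.columns)

    def to_tsv(self, path, raw_path=None) -> None:
        self.equalized.to_csv(path, sep="\t", index_label="window")
        if raw_path is not None:
            self.raw.to_csv(raw_path, sep="\t", index_label="window")

    @classmethod
    def from_tsv(cls, path, equalize_total: float = 10_000_000.0) -> "AccessibilityMatrix":
        eq = pd.read_csv(path, sep="\t", index_col="window")
        return cls(eq.copy(), eq, equalize_total)


def read_fragments(path) -> pd.DataFrame:
    """Read a fragments TSV(.gz): chrom, start, end, barcode[, support]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["Chromosome", "Start", "End", "Barcode"]
    if (df["Start"] >= df["End"]).any():
        raise ValueError("fragment with start >= end")
    return df


def aggregate_fragments(
    fragments: pd.DataFrame,
    annotation: CellAnnotation,
    windows: WindowSet,
) -> tuple[pd.DataFrame, int]:
    """Count fragments per (window, class) by fragment midpoint.

    Each fragment lands in the single window containing floor((start+end)/2).
    Fragments with unannotated barcodes or midpoints outside retained windows
    are counted as discarded. Returns (raw counts, discarded).
    """
    classes = annotation.classes
    counts = pd.DataFrame(
        np.zeros((windows.n, len(classes)), dtype=np.int64),
        index=pd.RangeIndex(windows.n, name="window"),
        columns=classes,
    )
    frag_class = fragments["Barcode"].map(annotation.barcode_to_class)
    annotated = frag_class.notna()
    discarded = int((~annotated).sum())
    frg = fragments[annotated]
    frag_class = frag_class[annotated]
    mid = (frg["Start"].to_numpy(np.int64) + frg["End"].to_numpy(np.int64)) // 2
    for chrom, idx in frg.groupby("Chromosome", sort=False).groups.items():
        ids = windows.locate(str(chrom), mid[frg.index.get_indexer(idx)])
        inside = ids >= 0
        discarded += int((~inside).sum())
        cls_codes = pd.Categorical(frag_class.loc[idx][inside], categories=classes).codes
        np.add.at(counts.values, (ids[inside], cls_codes), 1)
    return counts, discarded


def equalize(raw: pd.DataFrame, cfg: AtacConfig | None = None) -> AccessibilityMatrix:
    """Scale each class column to sum to cfg.equalize_total."""
    cfg = cfg or AtacConfig()
    sums = raw.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"cell classes with zero total counts: {zero}")
    eq = raw.astype(float) * (cfg.equalize_total / sums)
    return AccessibilityMatrix(raw.copy(), eq, cfg.equalize_total)
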