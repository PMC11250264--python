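"""Fixed-width genomic windows with mappability, gap and autosome filters.

The whole pipeline measures mutation density and chromatin accessibility
over one shared coordinate system: non-overlapping, fixed-width windows
(1 Mb by default) tiled across autosomes. Windows are removed when too few
of their bases are uniquely mappable, when they touch assembly gaps
(telomeres/centromeres), or when they lie on non-autosomes. All coordinates
are 0-based half-open (BED convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "Chromosome",
    "GenomeLayout",
    "WindowFilterConfig",
    "IntervalTrack",
    "WindowSet",
    "tile_windows",
    "mappable_fraction",
    "build_windows",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    autosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length")


@dataclass
class GenomeLayout:
    """Ordered chromosome names, lengths and autosome flags."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a chrom-sizes TSV: name, length and an optional autosome flag.

        Without the third column every chromosome whose name does not end in
        X/Y/M/MT is treated as an autosome.
        """
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        chroms = []
        for row in df.itertuples(index=False):
            name, length = str(row[0]), int(row[1])
            if len(row) >= 3 and not pd.isna(row[2]):
                auto = str(row[2]).strip().lower() in ("1", "true", "yes", "autosome")
            else:
                auto = name.removeprefix("chr").upper() not in ("X", "Y", "M", "MT")
            chroms.append(Chromosome(name, length, auto))
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length}\t{int(c.autosome)}\n")


@dataclass
class WindowFilterConfig:
    """Window construction parameters.

    min_mappable_fraction is the retention threshold: a window is kept when
    the fraction of its bases covered by the uniquely-mappable track is at
    least this value (the filter drops windows strictly below it). The
    mappability track is expected to derive from 36-mer uniqueness, but any
    precomputed uniquely-mappable BED is accepted.
    """

    window_size: int = 1_000_000
    min_mappable_fraction: float = 0.92
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 0 < self.min_mappable_fraction <= 1:
            raise ValueError("min_mappable_fraction must be in (0, 1]")


class IntervalTrack:
    """Sorted, merged set of genomic intervals (0-based half-open)."""

    def __init__(self, intervals: pd.DataFrame | None = None):
        if intervals is None or len(intervals) == 0:
            self.df = pd.DataFrame(columns=["Chromosome", "Start", "End"])
        else:
            df = intervals[["Chromosome", "Start", "End"]].copy()
            if (df["Start"] >= df["End"]).any():
                raise ValueError("interval with Start >= End")
            merged = pr.PyRanges(df).merge().df
            self.df = merged.sort_values(["Chromosome", "Start"]).reset_index(drop=True)
            self.df["Chromosome"] = self.df["Chromosome"].astype(str)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_intervals(cls, intervals) -> "IntervalTrack":
        """Build from an iterable of (chrom, start, end)."""
        rows = list(intervals)
        if not rows:
            return cls()
        df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
        return cls(df)

    @classmethod
    def from_bed(cls, path) -> "IntervalTrack":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             usecols=[0, 1, 2], names=["Chromosome", "Start", "End"])
        except pd.errors.EmptyDataError:
            return cls()
        return cls(df)

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def covered_bases(self, windows: pd.DataFrame) -> np.ndarray:
        """Bases of each window covered by the track.

        `windows` needs Chromosome/Start/End columns; returns an int array
        aligned with its rows.
        """
        out = np.zeros(len(windows), dtype=np.int64)
        if len(self.df) == 0 or len(windows) == 0:
            return out
        w = windows[["Chromosome", "Start", "End"]].copy()
        w["_row"] = np.arange(len(w))
        hits = pr.PyRanges(w).intersect(pr.PyRanges(self.df)).df
        if len(hits) == 0:
            return out
        per_row = (hits["End"] - hits["Start"]).groupby(hits["_row"]).sum()
        out[per_row.index.to_numpy()] = per_row.to_numpy()
        return out


def tile_windows(layout: GenomeLayout, cfg: WindowFilterConfig) -> pd.DataFrame:
    """Tile each chromosome from 0 in steps of window_size.

    Trailing partial windows are dropped so every feature shares one length
    scale; non-autosomes are skipped when cfg.autosomes_only. A chromosome
    shorter than one window simply contributes no windows.
    """
    if not layout.chromosomes:
        raise ValueError("empty genome layout")
    rows = []
    for c in layout.chromosomes:
        if cfg.autosomes_only and not c.autosome:
            continue
        n = c.length // cfg.window_size
        starts = np.arange(n, dtype=np.int64) * cfg.window_size
        for s in starts:
            rows.append((c.name, int(s), int(s) + cfg.window_size))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])


def mappable_fraction(window: tuple[str, int, int], track: IntervalTrack) -> float:
    """Fraction of the window's bases covered by the (merged) track."""
    chrom, start, end = window
    df = pd.DataFrame({"Chromosome": [chrom], "Start": [start], "End": [end]})
    covered = track.covered_bases(df)[0]
    return float(covered) / float(end - start)


@dataclass
class WindowSet:
    """Retained windows (dense ids 0..n-1) plus per-window exclusion records.

    `windows` columns: Chromosome, Start, End, Id, MappableFraction.
    `dropped` columns: Chromosome, Start, End, Reason — one of
    lowmap | gap_overlap | non_autosome | partial.
    """

    windows: pd.DataFrame
    dropped: pd.DataFrame
    window_size: int
    chromosomes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        w = self.windows
        if len(w) and not (w["Id"].to_numpy() == np.arange(len(w))).all():
            raise ValueError("window ids must be dense 0..n-1")
        if not self.chromosomes:
            self.chromosomes = frozenset(w["Chromosome"]) | frozenset(
                self.dropped["Chromosome"] if len(self.dropped) else []
            )
        # per-chromosome lookup: sorted retained starts -> window id
        self._starts: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        for chrom, grp in w.groupby("Chromosome", sort=False):
            order = np.argsort(grp["Start"].to_numpy())
            self._starts[chrom] = grp["Start"].to_numpy()[order]
            self._ids[chrom] = grp["Id"].to_numpy()[order]

    @property
    def n(self) -> int:
        return len(self.windows)

    def locate(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Window id containing each 0-based position; -1 if in no retained window.

        Raises KeyError for a chromosome absent from the tiled layout.
        """
        if chrom not in self.chromosomes:
            raise KeyError(f"chromosome {chrom!r} not in the window layout")
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.full(pos0.shape, -1, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None:  # chromosome known but all its windows dropped
            return out
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < starts[idx[ok]] + self.window_size
        out[ok] = self._ids[chrom][idx[ok]]
        return out

    def to_bed(self, path) -> None:
        df = self.windows[["Chromosome", "Start", "End", "Id", "MappableFraction"]]
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")

    @classmethod
    def from_bed(cls, path, window_size: int | None = None) -> "WindowSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["Chromosome", "Start", "End", "Id", "MappableFraction"])
        if window_size is None:
            window_size = int((df["End"] - df["Start"]).iloc[0])
        dropped = pd.DataFrame(columns=["Chromosome", "Start", "End", "Reason"])
        return cls(df, dropped, window_size)

    def exclusions_tsv(self, path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)


def build_windows(
    layout: GenomeLayout,
    mappability: IntervalTrack,
    gaps: IntervalTrack,
    cfg: WindowFilterConfig,
) -> WindowSet:
    """Tile, then filter: keep a window iff its mappable fraction is at least
    cfg.min_mappable_fraction, it overlaps the gap track by zero bases, and it
    lies on an autosome. Both filters are computed independently on the tiled
    windows; any gap overlap of one base or more excludes the window.
    """
    tiled = tile_windows(layout, cfg)
    dropped_rows = []

    if cfg.autosomes_only:
        # non-autosomes never enter `tiled`; record them for the audit trail
        for c in layout.chromosomes:
            if not c.autosome:
                n = c.length // cfg.window_size
                for i in range(n):
                    dropped_rows.append(
                        (c.name, i * cfg.window_size, (i + 1) * cfg.window_size, "non_autosome")
                    )

    frac = mappability.covered_bases(tiled) / cfg.window_size
    gap_bases = gaps.covered_bases(tiled)

    keep = (frac >= cfg.min_mappable_fraction) & (gap_bases == 0)
    for i in np.flatnonzero(~keep):
        reason = "gap_overlap" if gap_bases[i] > 0 else "lowmap"
        row = tiled.iloc[i]
        dropped_rows.append((row["Chromosome"], int(row["Start"]), int(row["End"]), reason))

    retained = tiled[keep].reset_index(drop=True)
    if len(retained) == 0:
        raise ValueError("no windows survive filtering; pipeline cannot proceed")
    retained["Id"] = np.arange(len(retained))
    retained["MappableFraction"] = frac[keep]

    dropped = pd.DataFrame(dropped_rows, columns=["Chromosome", "Start", "End", "Reason"])
    return WindowSet(retained, dropped, cfg.window_size, frozenset(layout.names))
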