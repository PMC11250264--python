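"""Cohort-level statistics: differential windows, TMB comparison, and the
origin-by-cohort contingency test.

Differential windows and the tumor-mutational-burden comparison use the
two-sided Wilcoxon rank-sum test (exact null when both groups are small and
untied, normal approximation with tie and continuity corrections otherwise).
Predicted origins are aggregated into a cohorts x origins table and tested
with Fisher's exact test: full enumeration of tables with the observed
margins when the total is small, seeded Monte-Carlo sampling from the
fixed-margin null otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import CooPrediction

__all__ = [
    "DiffWindowConfig",
    "ContingencyResult",
    "CohortSummary",
    "diff_windows",
    "compare_tmb",
    "origin_contingency",
    "fisher_exact_enum",
    "fisher_exact_mc",
    "rank_sum_test",
]

EXACT_MAX_GROUP = 10  # exact rank-sum null when both groups at most this and no ties
ENUM_MAX_TOTAL = 40  # full contingency enumeration up to this table total
MC_DRAWS = 100_000
_REL_TOL = 1e-7  # tables whose probability is within this of the observed count as extreme


@dataclass
class DiffWindowConfig:
    alpha: float = 0.01
    adjust: str = "none"  # "none" matches the raw P < alpha rule; BH reported alongside

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both groups have at most EXACT_MAX_GROUP
    observations and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def diff_windows(norm_matrix: pd.DataFrame, labels: pd.Series,
                 cfg: DiffWindowConfig | None = None) -> pd.DataFrame:
    """Per-window two-sided rank-sum test between the two cohorts.

    Returns one row per window: group medians of normalized density, the
    rank-sum statistic, raw p, BH-adjusted p, and the significance flag
    (raw p < alpha by default, matching the unadjusted screening rule).
    """
    cfg = cfg or DiffWindowConfig()
    labels = labels.reindex(norm_matrix.index)
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two cohorts, got {list(groups)}")
    ga, gb = sorted(groups)
    a = norm_matrix.loc[labels == ga].to_numpy(dtype=float)
    b = norm_matrix.loc[labels == gb].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 tumors")
    rows = []
    for j in range(norm_matrix.shape[1]):
        stat, p = rank_sum_test(a[:, j], b[:, j])
        rows.append((np.median(a[:, j]), np.median(b[:, j]), stat, p))
    out = pd.DataFrame(rows, columns=[f"median_{ga}", f"median_{gb}", "statistic", "p"],
                       index=norm_matrix.columns)
    out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    pcol = "p_bh" if cfg.adjust == "BH" else "p"
    out["significant"] = out[pcol] < cfg.alpha
    return out


@dataclass
class TmbComparison:
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    statistic: float
    p: float


def compare_tmb(tmb: pd.Series, labels: pd.Series) -> TmbComparison:
    """Two-sided rank-sum test on per-tumor clonal variant counts."""
    labels = labels.reindex(tmb.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two cohorts, got {groups}")
    ga, gb = groups
    a = tmb[labels == ga].to_numpy(dtype=float)
    b = tmb[labels == gb].to_numpy(dtype=float)
    stat, p = rank_sum_test(a, b)
    return TmbComparison(ga, gb, float(np.median(a)), float(np.median(b)), stat, p)


# ---------------------------------------------------------------- Fisher exact


def _log_table_prob(tables: np.ndarray, logfact_margins: float) -> np.ndarray:
    """log P(table) under the fixed-margin null, vectorized over leading axes."""
    return logfact_margins - gammaln(tables + 1.0).sum(axis=(-2, -1))


def _logfact_margins(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1))


def fisher_exact_enum(table: np.ndarray) -> float:
    """Exact Fisher p for an r x c table by full enumeration.

    Sums the null probability of every table with the observed margins whose
    probability does not exceed the observed table's (within a relative
    tolerance guarding against floating-point noise).
    """
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    lf = _logfact_margins(table)
    log_obs = _log_table_prob(table, lf)
    cutoff = log_obs + np.log1p(_REL_TOL)

    r, c = table.shape
    total_p = 0.0
    work = np.zeros((r, c), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray) -> None:
        nonlocal total_p
        if i == r - 1:
            work[i] = remaining_cols
            lp = _log_table_prob(work, lf)
            if lp <= cutoff:
                total_p += float(np.exp(lp))
            return
        for row_fill in _compositions(int(rows[i]), remaining_cols):
            work[i] = row_fill
            fill_row(i + 1, remaining_cols - row_fill)

    fill_row(0, cols.copy())
    return min(total_p, 1.0)


def _compositions(total: int, caps: np.ndarray):
    """All ways to write `total` as an ordered sum bounded cellwise by caps."""
    k = len(caps)
    cell = np.zeros(k, dtype=np.int64)
    suffix = np.concatenate([np.cumsum(caps[::-1])[::-1][1:], [0]])

    def rec(j: int, left: int):
        if j == k - 1:
            if left <= caps[j]:
                cell[j] = left
                yield cell.copy()
            return
        lo = max(0, left - int(suffix[j]))
        hi = min(int(caps[j]), left)
        for v in range(lo, hi + 1):
            cell[j] = v
            yield from rec(j + 1, left - v)

    yield from rec(0, total)


def fisher_exact_mc(table: np.ndarray, n_draws: int = MC_DRAWS,
                    seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo Fisher p: sample tables from the fixed-margin null.

    Returns (p, standard error). Uses the add-one estimator so p is never
    exactly zero.
    """
    table = np.asarray(table, dtype=np.int64)
    lf = _logfact_margins(table)
    log_obs = _log_table_prob(table, lf)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    lp = _log_table_prob(draws, lf)
    hits = int((lp <= log_obs + np.log1p(_REL_TOL)).sum())
    p = (hits + 1) / (n_draws + 1)
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return float(p), se


@dataclass
class ContingencyResult:
    p: float
    method: str  # "enumeration" | "monte-carlo" | "degenerate"
    se: float | None = None
    seed: int | None = None
    n_draws: int | None = None


@dataclass
class CohortSummary:
    """Cohorts x predicted-origins table with the exact-test result.

    `table` includes an 'abstained' column when any tumor abstained; the
    test itself runs on `tested_table` (abstentions excluded by default).
    """

    table: pd.DataFrame
    tested_table: pd.DataFrame
    result: ContingencyResult
    proportions: pd.DataFrame = field(default=None)

    @property
    def p(self) -> float:
        return self.result.p


def origin_contingency(predictions: list[CooPrediction], labels: pd.Series,
                       include_abstained: bool = False, seed: int = 0,
                       n_draws: int = MC_DRAWS) -> CohortSummary:
    """Aggregate predictions into a cohorts x origins table and test it.

    Exact p by full enumeration for 2x2 tables and whenever the tested total
    is at most ENUM_MAX_TOTAL; otherwise seeded Monte-Carlo with a reported
    standard error. A degenerate table (a single non-empty row or column)
    yields p = 1.
    """
    rows = []
    for pred in predictions:
        cohort = labels.get(pred.tumor_id)
        if cohort is None:
            raise KeyError(f"tumor {pred.tumor_id!r} missing from cohort labels")
        origin = "abstained" if pred.abstained else pred.origin
        rows.append((cohort, origin))
    df = pd.DataFrame(rows, columns=["cohort", "origin"])
    table = pd.crosstab(df["cohort"], df["origin"])

    tested = table if include_abstained else table.drop(columns=["abstained"], errors="ignore")
    # drop empty margins before testing
    tested = tested.loc[tested.sum(axis=1) > 0, tested.sum(axis=0) > 0]

    arr = tested.to_numpy(dtype=np.int64)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        import warnings

        warnings.warn("degenerate contingency table (single row or column); p = 1")
        result = ContingencyResult(1.0, "degenerate")
    elif arr.shape == (2, 2) or arr.sum() <= ENUM_MAX_TOTAL:
        result = ContingencyResult(fisher_exact_enum(arr), "enumeration")
    else:
        p, se = fisher_exact_mc(arr, n_draws=n_draws, seed=seed)
        result = ContingencyResult(p, "monte-carlo", se=se, seed=seed, n_draws=n_draws)

    proportions = table.div(table.sum(axis=1), axis=0)
    return CohortSummary(table, tested, result, proportions)
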