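import numpy as np
import pandas as pd
import pytest

import coorigin as co


@pytest.fixture(scope="session")
def small_sim_config():
    """A small but signal-rich synthetic setup shared across tests."""
    return co.SimConfig(
        n_windows=120,
        coupling_beta=2.0,
        total_mutations=4000,
        lowmap_fraction=0.1,
        seed=11,
        cohort_spec=(co.CohortSpec("A", 4, {"goblet": 1.0}),),
    )


@pytest.fixture(scope="session")
def small_windows(small_sim_config):
    layout, mapp, gaps = co.simulate_reference(small_sim_config)
    return co.build_windows(layout, mapp, gaps, co.WindowFilterConfig())


@pytest.fixture(scope="session")
def small_access(small_sim_config, small_windows):
    return co.simulate_accessibility(small_sim_config, small_windows)


# ----------------------------------------------------------------- oracles


def bitmap_covered_bases(window, intervals):
    """Per-base bitmap oracle for interval coverage of one window.

    Only usable on small windows; independent of the pyranges-based
    implementation.
    """
    chrom, start, end = window
    bitmap = np.zeros(end - start, dtype=bool)
    for c, s, e in intervals:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            bitmap[lo - start:hi - start] = True
    return int(bitmap.sum())


def ranksum_p_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group labelings."""
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    m = len(x)
    mean = m * (n + 1) / 2
    obs_dev = abs(obs - mean)
    hits = total = 0
    for combo in combinations(range(n), m):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(w - mean) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def hypergeom_2x2_p(table):
    """Fisher two-sided p for a 2x2 table from hypergeometric tail sums."""
    from scipy.stats import hypergeom

    a = np.asarray(table)
    n1, n2 = a.sum(axis=1)
    k = a[:, 0].sum()
    n = a.sum()
    rv = hypergeom(n, n1, k)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a[0, 0])
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())
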