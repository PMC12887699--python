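"""Shared statistical primitives: rank-sum tests, hypergeometric tails, BH.

The rank-sum helper implements the exact two-sided test by full enumeration
of group assignments (midranks, so ties are handled) for small pooled sizes,
falling back to the tie-corrected normal approximation for larger samples.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ranksum_exact_p",
    "ranksum_p",
    "hypergeom_tails",
    "bh_adjust",
]


@lru_cache(maxsize=32)
def _combinations(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as an array of shape (C, k)."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def ranksum_exact_p(x, y) -> float:
    """Exact two-sided Wilcoxon rank-sum p by enumeration of assignments.

    Uses midranks so tied values are valid; the p-value is
    P(|W - E[W]| >= |w_obs - E[W]|) over all C(n, n_x) equally likely
    assignments of the pooled ranks to group x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    mu = nx * (n + 1) / 2.0
    dev = abs(float(ranks[:nx].sum()) - mu)
    combos = _combinations(n, nx)
    w = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(w - mu) >= dev - 1e-9))


def ranksum_p(x, y, exact_max_n: int = 20) -> float:
    """Two-sided rank-sum p: exact for pooled n <= exact_max_n, else asymptotic.

    The asymptotic branch is the tie- and continuity-corrected normal
    approximation of the Mann-Whitney U test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= exact_max_n:
        return ranksum_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def hypergeom_tails(universe_n: int, n_a: int, n_b: int, k: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) for X ~ Hypergeometric(universe_n, n_a, n_b)."""
    if n_a > universe_n or n_b > universe_n:
        raise ValueError(
            f"set sizes ({n_a}, {n_b}) exceed universe size {universe_n}"
        )
    p_enrich = float(stats.hypergeom.sf(k - 1, universe_n, n_a, n_b))
    p_deplete = float(stats.hypergeom.cdf(k, universe_n, n_a, n_b))
    # both tails include P(X = k); clip numerical overshoot
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (q >= p always holds)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]
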