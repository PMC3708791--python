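"""Shared statistical tests.

The rank-sum test here is used both for the volatile group comparisons and
for the inhibition-zone comparisons, so it lives in one place.  For small
samples (combined n <= ``exact_limit``) the null distribution is enumerated
exactly over all assignments of the pooled observations to the two groups;
for larger samples a normal approximation with tie correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "TTestResult",
    "rank_sum_test",
    "welch_ttest",
    "significance_stars",
]

#: combined sample size up to which the exact null is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group (midranks for ties)
    pvalue: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float


def rank_sum_test(x, y, exact_limit: int = EXACT_LIMIT) -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact enumeration of the permutation null for combined n <= exact_limit
    (ties handled through midranks); otherwise the normal approximation with
    tie correction (no continuity correction, to match the enumerated null
    in the limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0

    if n + m <= exact_limit:
        total = comb(n + m, n)
        dev = abs(w_obs - mu)
        hits = 0
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(w_obs, hits / total, "exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return RankSumResult(w_obs, float(res.pvalue), "normal")


def welch_ttest(x, y) -> TTestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test needs at least two observations per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def significance_stars(p: float, levels=(0.001, 0.01, 0.05)) -> str:
    """Star annotation: '***' below levels[0], '**' below [1], '*' below [2]."""
    if p < levels[0]:
        return "***"
    if p < levels[1]:
        return "**"
    if p < levels[2]:
        return "*"
    return ""
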