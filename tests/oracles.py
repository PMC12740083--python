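"""Independent brute-force oracles used to check the statistical core.

Everything here is computed by exhaustive enumeration or by a literal
transcription of a textbook definition, deliberately sharing no code with
the package implementation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.stats import rankdata


@lru_cache(maxsize=None)
def hypergeom_enumeration(N: int, M: int, n: int) -> tuple[float, ...]:
    """P(X = k) for k = 0..n by enumerating every size-n draw from N genes.

    The first M indices are the marked ("in stratum") genes; every
    combination is equally likely.
    """
    counts = [0] * (n + 1)
    total = 0
    for comb in itertools.combinations(range(N), n):
        k = sum(1 for e in comb if e < M)
        counts[k] += 1
        total += 1
    return tuple(c / total for c in counts)


def enum_pmf(N: int, M: int, n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return hypergeom_enumeration(N, M, n)[k]


def enum_p_over(N: int, M: int, n: int, k: int) -> float:
    pmf = hypergeom_enumeration(N, M, n)
    return sum(pmf[max(k, 0):]) if k <= n else 0.0


def enum_p_under(N: int, M: int, n: int, k: int) -> float:
    if k < 0:
        return 0.0
    pmf = hypergeom_enumeration(N, M, n)
    return sum(pmf[: min(k, n) + 1])


def bh_step_up(pvalues) -> list[float]:
    """Literal Benjamini–Hochberg step-up: adj_(i) = min_{j>=i} m*p_(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for pos in range(m - 1, -1, -1):
        running = min(running, m * p[order[pos]] / (pos + 1))
        adj_sorted[pos] = min(running, 1.0)
    out = [0.0] * m
    for pos, idx in enumerate(order):
        out[idx] = adj_sorted[pos]
    return out


@lru_cache(maxsize=None)
def _rank_sum_distribution(pooled: tuple, n1: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Distribution of the doubled-midrank sum of group 1 over all
    equally likely assignments of the pooled values to groups."""
    ranks = rankdata(np.array(pooled, dtype=float))
    doubled = np.round(2 * ranks).astype(int)
    n = len(pooled)
    sums: dict[int, int] = {}
    total = 0
    for comb in itertools.combinations(range(n), n1):
        s = int(doubled[list(comb)].sum())
        sums[s] = sums.get(s, 0) + 1
        total += 1
    keys = tuple(sorted(sums))
    probs = tuple(sums[k] / total for k in keys)
    return keys, probs


def mw_exact_enumeration(x, y) -> tuple[float, float]:
    """(U for group x, two-sided exact p) by full enumeration with midranks.

    p = min(1, 2*min(P(S <= s_obs), P(S >= s_obs))) where S is the group-1
    midrank sum under exchangeable assignment with the tie pattern fixed.
    """
    x = list(x)
    y = list(y)
    pooled = tuple(sorted(x + y))
    n1 = len(x)
    ranks = rankdata(np.array(x + y, dtype=float))
    s_obs = int(round(2 * ranks[:n1].sum()))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    keys, probs = _rank_sum_distribution(pooled, n1)
    cdf = sum(pr for k, pr in zip(keys, probs) if k <= s_obs)
    sf = sum(pr for k, pr in zip(keys, probs) if k >= s_obs)
    return float(u), min(1.0, 2.0 * min(cdf, sf))
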