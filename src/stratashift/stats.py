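"""Exact hypergeometric tail probabilities and FDR correction.

The over-/under-representation test asks: drawing n genes from a universe of
N genes of which M lie in a given stratum, how surprising is it to observe k
stratum genes in the draw?  The point probability is

    P(X = k) = C(M, k) C(N-M, n-k) / C(N, n),

and both one-sided tails include the observed count:
P(X >= k) for over-representation, P(X <= k) for under-representation.
Probabilities are computed from log-factorials (``gammaln``) and summed in
log space, so they remain exact to near machine precision even deep in the
tails.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

__all__ = [
    "hypergeom_pmf",
    "hypergeom_logpmf_vector",
    "p_over",
    "p_under",
    "tail_probabilities",
    "bh_fdr",
]


def _validate(N: int, M: int, n: int) -> None:
    if N < 0 or M < 0 or n < 0:
        raise DomainError(f"negative hypergeometric parameter: N={N}, M={M}, n={n}")
    if M > N or n > N:
        raise DomainError(f"require M <= N and n <= N: N={N}, M={M}, n={n}")


def support(N: int, M: int, n: int) -> tuple[int, int]:
    """Inclusive bounds of k with nonzero probability."""
    return max(0, n - (N - M)), min(M, n)


def _log_comb(a: float, b: np.ndarray | float) -> np.ndarray | float:
    return gammaln(a + 1) - gammaln(np.asarray(b) + 1) - gammaln(a - np.asarray(b) + 1)


def hypergeom_logpmf_vector(N: int, M: int, n: int) -> tuple[int, np.ndarray]:
    """Log-pmf over the whole support; returns (lo, logp) with logp[j] = log P(X = lo+j)."""
    _validate(N, M, n)
    lo, hi = support(N, M, n)
    ks = np.arange(lo, hi + 1)
    logp = _log_comb(M, ks) + _log_comb(N - M, n - ks) - _log_comb(N, n)
    return lo, logp


def hypergeom_pmf(N: int, M: int, n: int, k: int) -> float:
    """P(X = k); zero outside the support."""
    _validate(N, M, n)
    lo, hi = support(N, M, n)
    if k < lo or k > hi:
        return 0.0
    return float(
        np.exp(_log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n))
    )


def tail_probabilities(N: int, M: int, n: int, k: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)), both tails including the observed point.

    Each tail is summed directly in log space over its own side of the
    support, so neither is derived from the other by complementation.
    """
    _validate(N, M, n)
    lo, logp = hypergeom_logpmf_vector(N, M, n)
    hi = lo + len(logp) - 1
    if k <= lo:
        over = 1.0
    elif k > hi:
        over = 0.0
    else:
        over = float(np.exp(logsumexp(logp[k - lo:])))
    if k >= hi:
        under = 1.0
    elif k < lo:
        under = 0.0
    else:
        under = float(np.exp(logsumexp(logp[: k - lo + 1])))
    return min(over, 1.0), min(under, 1.0)


def p_over(N: int, M: int, n: int, k: int) -> float:
    """Over-representation tail P(X >= k)."""
    return tail_probabilities(N, M, n, k)[0]


def p_under(N: int, M: int, n: int, k: int) -> float:
    """Under-representation tail P(X <= k)."""
    return tail_probabilities(N, M, n, k)[1]


def tail_tables(N: int, M: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tails for every k in 0..n: (p_over[k], p_under[k]).

    Used by simulation code that evaluates many draws against one universe.
    Values for k outside the support follow the tail conventions (p_over = 1
    below the support, 0 above; p_under symmetric).
    """
    _validate(N, M, n)
    lo, logp = hypergeom_logpmf_vector(N, M, n)
    hi = lo + len(logp) - 1
    pmf = np.exp(logp)
    # suffix/prefix sums of the pmf; accumulate from the small end of each tail
    over_sup = np.cumsum(pmf[::-1])[::-1]
    under_sup = np.cumsum(pmf)
    over = np.zeros(n + 1)
    under = np.ones(n + 1)
    over[: lo + 1] = 1.0
    over[lo : hi + 1] = np.minimum(over_sup, 1.0)
    under[lo : hi + 1] = np.minimum(under_sup, 1.0)
    under[:lo] = 0.0
    if hi < n:
        over[hi + 1 :] = 0.0
    return over, under


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    adj_i = min_{j >= i} (m * p_(j) / j) after ascending sort, capped at 1.
    All inputs must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("bh_fdr expects a nonempty 1-D array of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
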