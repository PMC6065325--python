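"""Core statistical procedures: Mann-Whitney U, hypergeometric tail, one-way ANOVA.

These three tests carry the pipeline's inference (link enrichment, gene-set
over-representation, timepoint pre-filtering). They are implemented directly —
exact enumeration for small Mann-Whitney samples, log-space binomial
coefficients for the hypergeometric survival function, sums of squares for the
F statistic — with scipy supplying only the reference distributions (normal, F).
Each has an independent brute-force oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

__all__ = ["TestResult", "mann_whitney_u", "hypergeom_sf", "one_way_anova"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical test.

    statistic
        Test-specific value (U for Mann-Whitney, F for ANOVA).
    p_value
        Two-sided unless noted; lies in (0, 1] except for the degenerate
        zero-within-variance ANOVA case where 0.0 is flagged via ``method``.
    method
        How the p-value was obtained (``exact`` or ``normal-approximation``
        for Mann-Whitney; ``f-distribution``, ``degenerate-zero`` or
        ``degenerate-constant`` for ANOVA).
    sample_sizes
        Per-group sample sizes, in input order.
    """

    statistic: float
    p_value: float
    method: str
    sample_sizes: tuple[int, ...]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> TestResult:
    """Rank-sum test that two samples come from the same distribution.

    U is reported for the first sample. ``mode='exact'`` enumerates the
    permutation distribution of U over all assignments of the pooled
    (mid)ranks; ``mode='normal'`` uses the tie-corrected normal approximation
    with continuity correction. ``mode='auto'`` picks exact when
    n1 + n2 <= 12 and the pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size
    u_obs = _u_from_ranks(float(ranks[:n1].sum()), n1)

    if mode == "auto":
        mode = "exact" if (n1 + n2 <= _EXACT_MAX_N and not has_ties) else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "exact":
        p = _mwu_exact_p(ranks, n1, u_obs, alternative)
        return TestResult(u_obs, p, "exact", (n1, n2))

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return TestResult(u_obs, 1.0, "normal-approximation", (n1, n2))
    sd = math.sqrt(var)
    dev = u_obs - mu
    if alternative == "two-sided":
        z = (abs(dev) - 0.5) / sd
        p = 2.0 * norm_dist.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (dev - 0.5) / sd
        p = norm_dist.sf(z)
    else:
        z = (dev + 0.5) / sd
        p = norm_dist.cdf(z)
    return TestResult(u_obs, float(min(p, 1.0)), "normal-approximation", (n1, n2))


def _mwu_exact_p(ranks: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    """Exact permutation p by enumerating which pooled ranks go to sample 1."""
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    base = n1 * (n1 + 1) / 2.0
    total = 0
    extreme = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - base
        total += 1
        if alternative == "two-sided":
            if abs(u - mu) >= abs(u_obs - mu) - eps:
                extreme += 1
        elif alternative == "greater":
            if u >= u_obs - eps:
                extreme += 1
        else:
            if u <= u_obs + eps:
                extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, m).

    N: population size; K: number of marked items; m: draws without
    replacement; k: observed marked draws. Computed in log space from
    binomial coefficients for stability at population sizes in the hundreds.
    """
    for name, v in (("k", k), ("N", N), ("K", K), ("m", m)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    k, N, K, m = int(k), int(N), int(K), int(m)
    if K > N or m > N:
        raise ValueError(f"inconsistent counts: K={K}, m={m} must not exceed N={N}")
    if k > min(m, K):
        raise ValueError(f"k={k} exceeds min(m={m}, K={K})")
    lo = max(0, m + K - N)
    hi = min(m, K)
    if k <= lo:
        return 1.0
    log_denom = _log_comb(N, m)
    log_terms = [
        _log_comb(K, i) + _log_comb(N - K, m - i) - log_denom for i in range(k, hi + 1)
    ]
    peak = max(log_terms)
    p = math.exp(peak) * sum(math.exp(t - peak) for t in log_terms)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across two or more groups.

    F = MSB/MSW with (g-1, n-g) degrees of freedom. Degenerate inputs:
    zero within-group variance with unequal means gives p = 0 (flagged as
    ``degenerate-zero``); all values identical gives F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one_way_anova requires at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    sizes = tuple(a.size for a in arrays)
    n = sum(sizes)
    g = len(arrays)
    grand = sum(float(a.sum()) for a in arrays) / n
    ssb = sum(a.size * (float(a.mean()) - grand) ** 2 for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    dfb, dfw = g - 1, n - g
    if ssw <= 0.0:
        if ssb <= 0.0:
            return TestResult(0.0, 1.0, "degenerate-constant", sizes)
        return TestResult(math.inf, 0.0, "degenerate-zero", sizes)
    f_stat = (ssb / dfb) / (ssw / dfw)
    p = float(f_dist.sf(f_stat, dfb, dfw))
    return TestResult(f_stat, max(p, 0.0), "f-distribution", sizes)
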