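"""Spectrum statistics: bootstrap proportion CI, subtype-rate propagation,
Fisher's exact and Mann-Whitney tests.

The foldback inversion rate q is the product of the overall GCR rate r
(from fluctuation analysis) and the foldback proportion p (from the
observed GCR spectrum).  The 95% CI of p comes from a bootstrap of the 0/1
observations with a pseudo-count guard at the boundaries, and the CI of q
propagates the relative half-widths of both intervals in quadrature:

    q    = r p
    q_lo = q - q sqrt(((r - r_lo)/r)^2 + ((p - p_lo)/p)^2)
    q_hi = q + q sqrt(((r - r_hi)/r)^2 + ((p - p_hi)/p)^2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from ._rng import substream
from .fluctuation import RateEstimate

DEFAULT_BOOTSTRAP_RESAMPLES = 100_000

#: relative tolerance when comparing hypergeometric point probabilities
_FISHER_RELTOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ProportionCI:
    """Bootstrap 95% CI for the foldback proportion k/n."""

    k: int
    n: int
    p: float
    p_lo: float
    p_hi: float
    pseudo_applied: bool
    B: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo <= self.p <= self.p_hi <= 1.0):
            raise ValueError("proportion CI must satisfy 0 <= lo <= p <= hi <= 1")


@dataclass(frozen=True)
class SubtypeRate:
    """Foldback inversion rate q = r*p with propagated 95% bounds."""

    q: float
    q_lo: float
    q_hi: float
    floored: bool = False

    def __post_init__(self) -> None:
        if not (self.q_lo <= self.q <= self.q_hi):
            raise ValueError("subtype rate CI must bracket the point estimate")


def bootstrap_proportion_ci(
    k: int,
    n: int,
    B: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    seed: int | np.random.Generator = 0,
) -> ProportionCI:
    """Bootstrap CI for a proportion from k successes in n observations.

    B resamples of size n are drawn with replacement from the n 0/1
    observations; the CI is the empirical 0.025/0.975 quantile of the
    resample proportions.  When k is 0 or n, one observation of the
    missing class is added first (pseudo-count; n grows by one) so the
    interval cannot degenerate to a point.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if n < 1:
        raise ValueError("need n >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else substream(int(seed), "bootstrap")
    )
    pseudo = k == 0 or k == n
    k2, n2 = k, n
    if pseudo:
        n2 = n + 1
        if k == 0:
            k2 = 1
        # k == n: the added observation is a non-foldback; k2 stays k
    p_hat = k2 / n2
    draws = rng.binomial(n2, p_hat, size=B) / n2
    p_lo, p_hi = np.quantile(draws, [0.025, 0.975])
    return ProportionCI(
        k=k, n=n, p=p_hat, p_lo=float(p_lo), p_hi=float(p_hi),
        pseudo_applied=pseudo, B=B,
    )


def propagate_subtype_rate(rate: RateEstimate, prop: ProportionCI) -> SubtypeRate:
    """Combine a GCR rate CI and a foldback proportion CI into a subtype rate.

    Follows the corrected error-propagation equations (relative interval
    half-widths added in quadrature).  A formula result below zero is
    floored at 0 and flagged.
    """
    r, r_lo, r_hi = rate.r, rate.r_lo, rate.r_hi
    p, p_lo, p_hi = prop.p, prop.p_lo, prop.p_hi
    if r <= 0:
        raise ValueError(
            "r must be positive; all-zero fluctuation data needs the boundary "
            "rate handling in estimate_rate"
        )
    if p <= 0:
        raise ValueError("p must be positive; apply the pseudo-count path for k=0")
    q = r * p
    q_lo = q - q * np.sqrt(((r - r_lo) / r) ** 2 + ((p - p_lo) / p) ** 2)
    q_hi = q + q * np.sqrt(((r - r_hi) / r) ** 2 + ((p - p_hi) / p) ** 2)
    floored = q_lo < 0
    return SubtypeRate(
        q=float(q), q_lo=float(max(q_lo, 0.0)), q_hi=float(q_hi), floored=bool(floored)
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    All tables with the observed margins whose hypergeometric point
    probability is at most that of the observed table (within a 1+1e-7
    relative tolerance) contribute to p.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        raise ValueError("at least one margin must be positive")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = sp_stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = probs[support == a][0]
    p = float(probs[probs <= p_obs * _FISHER_RELTOL].sum())
    return min(p, 1.0)


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U test p-value.

    Exact enumeration when the smaller sample has at most 8 observations
    and there are no ties across samples; otherwise the tie-corrected
    normal approximation.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
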