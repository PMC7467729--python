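"""Luria-Delbruck fluctuation analysis: simulation and rate estimation.

The number of mutants in a parallel culture follows the Luria-Delbruck
distribution with parameter m (expected mutations per culture).  Its pmf
obeys the standard recursion

    p_0 = exp(-m),    p_r = (m / r) * sum_{i=0}^{r-1} p_i / (r - i + 1)

equivalently, the count is a compound Poisson(m) sum of clone sizes with
P(clone = k) = 1 / (k (k + 1)) — the form used for exact sampling, since
the clone-size law is so heavy-tailed (P(clone >= k) = 1/k) that the pmf
cannot be tabulated to the far tail.  Rates are estimated by the
Ma-Sandri-Sarkar maximum-likelihood method with jackpot counts censored at
a cap, and the 95% confidence interval uses the standard log-scale
approximation sigma_ln(m) = 1.225 m^-0.315 / sqrt(C) for C cultures.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from ._rng import substream

#: counts above this are treated as censored jackpots in the likelihood
DEFAULT_COUNT_CAP = 1000


@dataclass(frozen=True)
class FluctuationData:
    """Mutant counts per culture plus cells per culture N."""

    counts: tuple[int, ...]
    cells_per_culture: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("mutant counts must be non-negative")
        if self.cells_per_culture <= 0:
            raise ValueError("cells per culture must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """MSS-MLE mutation rate with a 95% confidence interval.

    ``m`` is expected mutations per culture, ``r = m / N`` the rate per
    cell division.  ``m_p0`` is the p0-method estimate -ln(fraction of
    zero-count cultures) when any culture had zero mutants, else None.
    """

    m: float
    r: float
    r_lo: float
    r_hi: float
    n_cultures: int
    m_p0: float | None = None
    all_zero: bool = False

    def __post_init__(self) -> None:
        if not (self.r_lo <= self.r <= self.r_hi):
            raise ValueError("rate CI must bracket the point estimate")


def luria_delbruck_pmf(m: float, rmax: int, tail: float = 1e-9) -> np.ndarray:
    """pmf of mutant counts 0..rmax by the standard recursion.

    Computation stops early once the accumulated mass exceeds ``1 - tail``;
    the returned array is zero beyond that point.  The mass above rmax is
    ``1 - pmf.sum()`` (the distribution's tail decays only like m/r, so a
    far-tail tabulation is not practical; jackpots are handled by
    censoring, and sampling uses the exact compound-Poisson form).
    """
    if m <= 0:
        raise ValueError("m must be positive")
    p = np.zeros(rmax + 1)
    p[0] = np.exp(-m)
    cum = p[0]
    # weights w[i] = 1/(r - i + 1) built incrementally per r
    for r in range(1, rmax + 1):
        i = np.arange(r)
        p[r] = (m / r) * np.dot(p[:r], 1.0 / (r - i + 1))
        cum += p[r]
        if cum > 1.0 - tail:
            break
    return p


def simulate_fluctuation_experiment(
    m: float,
    n_cultures: int,
    seed: int | np.random.Generator = 0,
) -> list[int]:
    """Exact mutant counts for parallel cultures at parameter ``m``.

    Each culture receives Poisson(m) mutations; each mutation founds a
    clone of size floor(1/U), U ~ Uniform(0,1), which realises the
    clone-size law P(k) = 1/(k(k+1)) of the Luria-Delbruck model.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else substream(int(seed), "fluctuation")
    )
    counts: list[int] = []
    n_mutations = rng.poisson(m, size=n_cultures)
    for k in n_mutations:
        if k == 0:
            counts.append(0)
            continue
        u = rng.random(k)
        counts.append(int(np.sum(np.floor(1.0 / u))))
    return counts


def estimate_rate(
    data: FluctuationData,
    count_cap: int = DEFAULT_COUNT_CAP,
) -> RateEstimate:
    """Ma-Sandri-Sarkar maximum-likelihood rate estimate with 95% CI.

    The likelihood is maximised by golden-section search on ln m over
    [1e-4, 50]; counts above ``count_cap`` contribute the censored tail
    mass P(count > cap).  All-zero data yield r = 0 with r_hi from the
    p0 bound (the largest m whose probability of seeing C zero cultures
    is at least 2.5%).
    """
    counts = np.asarray(data.counts)
    C = len(counts)
    if C < 5:
        raise ValueError("need at least 5 cultures for a fluctuation estimate")
    N = data.cells_per_culture

    frac_zero = float(np.mean(counts == 0))
    m_p0 = -float(np.log(frac_zero)) if 0 < frac_zero else None

    if np.all(counts == 0):
        # P(all zero | m) = exp(-C m) >= 0.025  =>  m <= -ln(0.025)/C
        m_hi = -np.log(0.025) / C
        return RateEstimate(
            m=0.0, r=0.0, r_lo=0.0, r_hi=m_hi / N,
            n_cultures=C, m_p0=m_p0, all_zero=True,
        )

    capped = np.minimum(counts, count_cap)
    censored = counts > count_cap
    uniq, inv = np.unique(capped, return_inverse=True)
    rmax = int(uniq.max())

    def negloglik(log_m: float) -> float:
        m = np.exp(log_m)
        pmf = luria_delbruck_pmf(m, rmax, tail=0.0)
        tail_mass = max(1.0 - pmf.sum(), 1e-300)
        probs = np.maximum(pmf[uniq][inv], 1e-300)
        ll = np.where(censored, np.log(tail_mass), np.log(probs))
        return -float(ll.sum())

    log_m = _golden_section(negloglik, np.log(1e-4), np.log(50.0))
    m = float(np.exp(log_m))

    sigma = 1.225 * m ** (-0.315) / np.sqrt(C)
    m_lo = m * np.exp(-1.96 * sigma)
    m_hi = m * np.exp(1.96 * sigma)
    return RateEstimate(
        m=m, r=m / N, r_lo=m_lo / N, r_hi=m_hi / N, n_cultures=C, m_p0=m_p0
    )


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Minimise a unimodal function on [lo, hi]."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return (a + b) / 2.0
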