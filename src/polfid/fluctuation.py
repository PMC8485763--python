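"""Luria–Delbrück fluctuation analysis with partial plating.

The mutant-count distribution is modeled as a compound Poisson: the number of
mutational events per culture is Poisson(m), and each event founds a clone
whose final size follows the Lea–Coulson law P(Y = y) = 1/[y(y+1)] (the
deterministic-growth limit Y = floor(1/U)). When only a fraction ``epsilon`` of
the culture is plated, each clone contributes Binomial(Y, epsilon) observable
colonies. For epsilon = 1 the distribution reduces to the classic
Ma–Sandri–Sarkar (MSS) recursion

    p_0 = exp(-m),    p_n = (m/n) * sum_{i=0}^{n-1} p_i / (n - i + 1).

Estimation is by maximum likelihood in m with profile-likelihood confidence
intervals; strains are compared with a likelihood-ratio test on the mutation
rate mu = m / N_t, and families of comparisons are adjusted with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, NumericalError, ParameterError

__all__ = [
    "FluctuationExperiment",
    "MLEResult",
    "RateEstimate",
    "ld_pmf",
    "log_likelihood",
    "estimate_m",
    "rate_from_m",
    "estimate_rate",
    "lrt_rates",
    "bh_adjust",
]

# half of the chi-square(1) 0.95 quantile, the profile-likelihood CI drop
_CHI2_DROP = float(stats.chi2.ppf(0.95, df=1)) / 2.0

#: counts at or above this value are treated as right-censored ("jackpot"
#: cultures); they enter the likelihood through the upper-tail probability.
DEFAULT_CENSOR_AT = 1000


@dataclass(frozen=True)
class FluctuationExperiment:
    """Resistant-colony counts from one set of parallel cultures.

    Parameters
    ----------
    counts
        Number of resistant colonies observed per culture (non-negative ints).
    epsilon
        Fraction of each culture that was plated, in (0, 1].
    Nt
        Mean final number of cells per culture (from CFU titers).
    label
        Strain / condition identifier.
    """

    counts: tuple[int, ...]
    epsilon: float = 1.0
    Nt: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise DataError("counts must be non-empty")
        if any(c < 0 for c in counts):
            raise DataError("counts must be non-negative integers")
        if not (0.0 < self.epsilon <= 1.0):
            raise ParameterError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if not self.Nt > 0:
            raise ParameterError(f"Nt must be positive, got {self.Nt}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class MLEResult:
    """Maximum-likelihood fit of the expected mutations per culture."""

    m_hat: float
    ci_low: float
    ci_high: float
    loglik: float


@dataclass(frozen=True)
class RateEstimate:
    """Mutation rate per cell per generation, mu = m / N_t, with 95% CI."""

    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    loglik: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ParameterError("rate CI must bracket the point estimate")


@lru_cache(maxsize=64)
def _clone_contribution_pmf(epsilon: float, n_max: int, tol: float = 1e-10) -> tuple[float, ...]:
    """Distribution h_k of *observed* colonies from a single mutant clone.

    Obtained by Binomial(y, epsilon) thinning of the Lea–Coulson clone-size law
    P(Y=y) = 1/[y(y+1)], summed over y until the remaining tail can contribute
    less than ``tol`` to any class k <= n_max (P(Y>y) = 1/(y+1) and the
    binomial CDF at n_max is decreasing in y).
    """
    if epsilon == 1.0:
        h = np.zeros(n_max + 1)
        j = np.arange(1, n_max + 1)
        h[1:] = 1.0 / (j * (j + 1.0))
        return tuple(h)
    h = np.zeros(n_max + 1)
    k = np.arange(n_max + 1)
    y = 1
    while True:
        w = 1.0 / (y * (y + 1.0))  # P(Y = y)
        h += w * stats.binom.pmf(k, y, epsilon)
        # tail bound: every y' > y contributes at most P(Y>y)*CDF(n_max; y, eps)
        if (1.0 / (y + 1.0)) * stats.binom.cdf(n_max, y, epsilon) < tol:
            break
        y += 1
        if y > 10_000_000:  # pragma: no cover - defensive
            raise NumericalError("clone-contribution pmf did not converge")
    return tuple(h)


def ld_pmf(m: float, epsilon: float = 1.0, n_max: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Mutant-count pmf p_0..p_{n_max} under the Luria–Delbrück model.

    For ``epsilon == 1`` this equals the MSS recursion term by term; for
    partial plating it is the Poisson(m) compound of the thinned clone law,
    evaluated with the Panjer recursion.
    """
    if m < 0:
        raise ParameterError(f"m must be >= 0, got {m}")
    if not (0.0 < epsilon <= 1.0):
        raise ParameterError(f"epsilon must be in (0, 1], got {epsilon}")
    if n_max < 0:
        raise ParameterError("n_max must be >= 0")
    h = np.asarray(_clone_contribution_pmf(float(epsilon), int(n_max), tol))
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m * (1.0 - h[0]))
    if m == 0.0:
        return p
    w = np.arange(n_max + 1) * h  # j * h_j, the Panjer weights
    for n in range(1, n_max + 1):
        p[n] = (m / n) * float(np.dot(w[1 : n + 1], p[n - 1 :: -1][:n]))
    return p


def log_likelihood(
    m: float,
    exp: FluctuationExperiment,
    censor_at: int | None = DEFAULT_CENSOR_AT,
) -> float:
    """Log-likelihood of ``m`` for one experiment.

    Counts at or above ``censor_at`` are treated as right-censored and
    contribute log P(X >= censor_at); pass ``censor_at=None`` for the exact
    (uncensored) likelihood.
    """
    counts = np.asarray(exp.counts)
    if censor_at is not None:
        cens_n = int(np.sum(counts >= censor_at))
        obs = counts[counts < censor_at]
    else:
        cens_n = 0
        obs = counts
    if m == 0.0:
        return 0.0 if (cens_n == 0 and np.all(obs == 0)) else -np.inf
    n_max = int(max(obs.max() if obs.size else 0, (censor_at - 1) if cens_n else 0))
    p = ld_pmf(m, exp.epsilon, n_max)
    ll = 0.0
    if obs.size:
        uniq, mult = np.unique(obs, return_counts=True)
        ll += float(np.dot(mult, np.log(np.maximum(p[uniq], 1e-300))))
    if cens_n:
        tail = max(1.0 - float(p.sum()), 1e-300)
        ll += cens_n * math.log(tail)
    return ll


def _initial_m(exp: FluctuationExperiment) -> float:
    zero_frac = exp.counts.count(0) / len(exp.counts)
    if zero_frac > 0.0:
        h0 = _clone_contribution_pmf(float(exp.epsilon), 0)[0]
        m0 = -math.log(zero_frac) / (1.0 - h0) if zero_frac < 1.0 else 0.0
        return max(m0, 1e-3)
    return 1.0


def estimate_m(
    exp: FluctuationExperiment,
    censor_at: int | None = DEFAULT_CENSOR_AT,
    compute_ci: bool = True,
) -> MLEResult:
    """Maximum-likelihood estimate of m with 95% profile-likelihood CI.

    The CI bounds solve l(m) = l(m_hat) - chi2_{1,0.95}/2 (= 1.9207). An
    all-zero experiment yields m_hat = 0 with ci_low = 0 and the upper bound
    from the closed-form zero-class likelihood.
    """
    counts = np.asarray(exp.counts)
    n = counts.size
    h0 = _clone_contribution_pmf(float(exp.epsilon), 0)[0]
    if np.all(counts == 0):
        # l(m) = -n m (1 - h0); drops by _CHI2_DROP at the upper bound
        hi = _CHI2_DROP / (n * (1.0 - h0)) if compute_ci else 0.0
        return MLEResult(m_hat=0.0, ci_low=0.0, ci_high=hi, loglik=0.0)

    def nll(m: float) -> float:
        return -log_likelihood(m, exp, censor_at)

    m0 = _initial_m(exp)
    lo, hi = m0 / 64.0, m0 * 4.0
    # expand the upper bracket until the likelihood is decreasing past it
    while nll(hi * 2.0) < nll(hi):
        hi *= 2.0
        if hi > 1e8:
            raise NumericalError("failed to bracket the likelihood maximum")
    res = optimize.minimize_scalar(
        nll, bounds=(min(lo, 1e-8), hi * 2.0), method="bounded",
        options={"xatol": 1e-9 * (1.0 + hi)},
    )
    if not res.success:  # pragma: no cover - bounded rarely fails
        raise NumericalError(f"likelihood maximization failed: {res.message}")
    m_hat = float(res.x)
    ll_max = -float(res.fun)
    if not compute_ci:
        return MLEResult(m_hat=m_hat, ci_low=math.nan, ci_high=math.nan, loglik=ll_max)

    target = ll_max - _CHI2_DROP

    def f(m: float) -> float:
        return log_likelihood(m, exp, censor_at) - target

    # lower bound: l -> -inf as m -> 0 because some count is positive
    a = m_hat
    while f(a / 2.0) > 0:
        a /= 2.0
        if a < 1e-12:
            break
    ci_low = 0.0 if a < 1e-12 else float(
        optimize.brentq(f, a / 2.0, m_hat, xtol=1e-8 * (1.0 + m_hat))
    )
    # upper bound: l -> -inf as m -> inf
    b = max(m_hat, 1e-6)
    while f(b * 2.0) > 0:
        b *= 2.0
        if b > 1e8:
            raise NumericalError("failed to bracket the upper CI bound")
    ci_high = float(optimize.brentq(f, b, b * 2.0, xtol=1e-8 * (1.0 + m_hat)))
    return MLEResult(m_hat=m_hat, ci_low=ci_low, ci_high=ci_high, loglik=ll_max)


def rate_from_m(
    m_hat: float, ci: tuple[float, float], Nt: float, loglik: float = math.nan, label: str = ""
) -> RateEstimate:
    """Convert an estimate of m into a per-cell per-generation rate mu = m/N_t."""
    if not Nt > 0:
        raise ParameterError(f"Nt must be positive, got {Nt}")
    lo, hi = ci
    return RateEstimate(
        m_hat=m_hat, rate=m_hat / Nt, ci_low=lo / Nt, ci_high=hi / Nt,
        loglik=loglik, label=label,
    )


def estimate_rate(
    exp: FluctuationExperiment, censor_at: int | None = DEFAULT_CENSOR_AT
) -> RateEstimate:
    """Fit m and report the mutation rate with its 95% CI."""
    fit = estimate_m(exp, censor_at=censor_at)
    return rate_from_m(
        fit.m_hat, (fit.ci_low, fit.ci_high), exp.Nt, loglik=fit.loglik, label=exp.label
    )


def lrt_rates(
    exp1: FluctuationExperiment,
    exp2: FluctuationExperiment,
    censor_at: int | None = DEFAULT_CENSOR_AT,
) -> tuple[float, float]:
    """Likelihood-ratio test of equal mutation rates between two experiments.

    Alternative: each experiment has its own rate mu_i (m_i = mu_i * Nt_i).
    Null: a shared mu. Returns (statistic, p) with p from the chi-square(1)
    upper tail.
    """
    fit1 = estimate_m(exp1, censor_at=censor_at, compute_ci=False)
    fit2 = estimate_m(exp2, censor_at=censor_at, compute_ci=False)
    ll_alt = fit1.loglik + fit2.loglik
    if fit1.m_hat == 0.0 and fit2.m_hat == 0.0:
        return 0.0, 1.0

    def nll_null(log_mu: float) -> float:
        mu = math.exp(log_mu)
        return -(
            log_likelihood(mu * exp1.Nt, exp1, censor_at)
            + log_likelihood(mu * exp2.Nt, exp2, censor_at)
        )

    mu0 = (fit1.m_hat + fit2.m_hat) / (exp1.Nt + exp2.Nt)
    mu0 = max(mu0, 1e-300)
    res = optimize.minimize_scalar(
        nll_null,
        bounds=(math.log(mu0) - 8.0, math.log(mu0) + 8.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    ll_null = -float(res.fun)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return stat, float(stats.chi2.sf(stat, df=1))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
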