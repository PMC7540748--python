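"""Frequentist and Bayesian inference on dependency scores.

One-sample and Welch two-sample t tests with Cohen's d, Jeffreys-Zellner-Siow
(JZS) Bayes factors for the one-sample contrast, prior-robustness sweeps, and
exact power/sample-size for the one-sample t via the noncentral t distribution.

The JZS Bayes factor places a Cauchy(0, r) prior on the standardised effect
delta = mu/sigma (default scale r = 0.707 = sqrt(2)/2). BF10 is the ratio of
the marginal likelihood of the observed t statistic under that prior,

    m1(t) = integral  T_{n-1}(t; ncp = delta * sqrt(n)) Cauchy(delta; 0, r) d delta,

to the central-t density m0(t) = T_{n-1}(t; ncp = 0); both are evaluated here
by adaptive quadrature over the effect. Reported as BF01 = 1/BF10, so values
above 1 favour the null (no dependency); BF01 > 3 is conventionally moderate
evidence for the null, BF01 < 1/3 moderate evidence for an effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "InferenceResult",
    "BFConfig",
    "one_sample_t",
    "cohens_d_from_t",
    "welch_t",
    "jzs_bf01",
    "jzs_bf10",
    "bf_robustness",
    "power_one_sample_t",
    "required_n",
]

DEFAULT_PRIOR_SCALE = 0.707


@dataclass(frozen=True)
class InferenceResult:
    """t-test summary: statistic, df, two-sided p, Cohen's d, optional BF01."""

    t: float
    df: float
    p_two_sided: float
    d: float
    n: int  # one-sample n, or n1 + n2 for two-sample
    bf01: float | None = None
    prior_scale: float | None = None

    @property
    def bf10(self) -> float | None:
        return None if self.bf01 is None else 1.0 / self.bf01


@dataclass(frozen=True)
class BFConfig:
    """Bayes-factor settings: Cauchy prior scale, robustness grid, quadrature tolerance."""

    prior_scale: float = DEFAULT_PRIOR_SCALE
    robustness_grid: tuple[float, ...] = (0.5, DEFAULT_PRIOR_SCALE, 1.0)
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.prior_scale <= 0 or self.tol <= 0:
            raise ValueError("prior_scale and tol must be positive")
        if any(r <= 0 for r in self.robustness_grid):
            raise ValueError("robustness grid entries must be positive")


def _check_sample(x: np.ndarray, label: str = "sample") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"{label} must be 1-D with at least 2 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError(f"{label} has zero variance; t statistic undefined")
    return x


def one_sample_t(
    values: Sequence[float],
    mu0: float = 0.0,
    *,
    prior_scale: float | None = DEFAULT_PRIOR_SCALE,
) -> InferenceResult:
    """Two-sided one-sample t test against ``mu0``, with Cohen's d and JZS BF01.

    Cohen's d is (mean - mu0) / sd, identically t / sqrt(n). Pass
    ``prior_scale=None`` to skip the Bayes factor.
    """
    x = _check_sample(np.asarray(values))
    n = x.size
    res = stats.ttest_1samp(x, mu0)
    t = float(res.statistic)
    bf01 = jzs_bf01(t, n, prior_scale) if prior_scale is not None else None
    return InferenceResult(
        t=t,
        df=float(n - 1),
        p_two_sided=float(res.pvalue),
        d=t / np.sqrt(n),
        n=n,
        bf01=bf01,
        prior_scale=prior_scale,
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """One-sample effect size from the t statistic: d = t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(t) / np.sqrt(n)


def welch_t(sample1: Sequence[float], sample2: Sequence[float]) -> InferenceResult:
    """Welch two-sample t test (Satterthwaite df) with pooled-sd Cohen's d."""
    x = _check_sample(np.asarray(sample1), "sample1")
    y = _check_sample(np.asarray(sample2), "sample2")
    res = stats.ttest_ind(x, y, equal_var=False)
    n1, n2 = x.size, y.size
    sp = np.sqrt(
        ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    )
    d = float((np.mean(x) - np.mean(y)) / sp)
    return InferenceResult(
        t=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
        d=d,
        n=n1 + n2,
    )


def jzs_bf10(
    t: float, n: int, r: float = DEFAULT_PRIOR_SCALE, *, tol: float = 1e-8
) -> float:
    """JZS one-sample Bayes factor BF10 for an observed t with sample size n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if r <= 0:
        raise ValueError("prior scale r must be positive")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, r)

    # centre the quadrature on the likelihood peak so narrow integrands are hit
    peak = t / sqrt_n
    marginal, err = integrate.quad(
        integrand, -np.inf, np.inf, points=None, epsabs=tol, epsrel=tol, limit=200,
    )
    if marginal <= 0:
        raise ArithmeticError("quadrature returned a nonpositive marginal likelihood")
    if err > max(tol, 1e-6 * marginal):
        # retry splitting at the peak before giving up
        left, e1 = integrate.quad(integrand, -np.inf, peak, epsabs=tol, epsrel=tol, limit=200)
        right, e2 = integrate.quad(integrand, peak, np.inf, epsabs=tol, epsrel=tol, limit=200)
        marginal, err = left + right, e1 + e2
        if err > max(tol, 1e-6 * marginal):
            raise ArithmeticError(
                f"quadrature did not converge: estimated error {err:.2e} for marginal {marginal:.2e}"
            )
    null_like = stats.t.pdf(t, df)
    return float(marginal / null_like)


def jzs_bf01(
    t: float, n: int, r: float = DEFAULT_PRIOR_SCALE, *, tol: float = 1e-8
) -> float:
    """JZS Bayes factor in favour of the null: BF01 = 1 / BF10."""
    return 1.0 / jzs_bf10(t, n, r, tol=tol)


def bf_robustness(
    t: float, n: int, r_grid: Sequence[float] = BFConfig().robustness_grid
) -> list[tuple[float, float]]:
    """BF01 across a grid of Cauchy prior widths, for prior-sensitivity checks."""
    grid = list(r_grid)
    if not grid or any(r <= 0 for r in grid):
        raise ValueError("r_grid must be non-empty with positive entries")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("r_grid must be strictly increasing")
    return [(float(r), jzs_bf01(t, n, r)) for r in grid]


def power_one_sample_t(
    n: int, d: float, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Exact power of the one-sample t test at effect size d.

    Uses the noncentral t distribution with noncentrality d*sqrt(n) and
    df = n - 1. At d = 0 the power equals alpha.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = d * np.sqrt(n)
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = (1 - stats.nct.cdf(tcrit, df, ncp)) + stats.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = stats.t.ppf(1 - alpha, df)
        power = 1 - stats.nct.cdf(tcrit, df, ncp)
    return float(power)


def required_n(
    d: float,
    target_power: float,
    alpha: float = 0.05,
    *,
    two_sided: bool = True,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n whose one-sample-t power at effect d reaches ``target_power``.

    Power is nondecreasing in n, so a bracket-doubling search followed by
    bisection finds the exact minimal n.
    """
    if d == 0:
        raise ValueError("power cannot exceed alpha at d = 0")
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    lo, hi = 2, 2
    while power_one_sample_t(hi, d, alpha, two_sided) < target_power:
        lo = hi
        hi *= 2
        if hi > max_n:
            raise ValueError(f"target power {target_power} not reachable below n = {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_one_sample_t(mid, d, alpha, two_sided) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi
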