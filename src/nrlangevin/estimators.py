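"""Time-average estimators, asymptotic-variance estimation, MSE, CIs.

Two routes to the asymptotic variance σ²_f of the CLT
√T(π_T(f) − π(f)) → N(0, σ²_f):

* ``ensemble_sigma2`` — T times the sample variance of π_T(f) across
  independent replicas of common length T;
* ``batch_means_sigma2`` — from a single trajectory: split the post-burn-in
  series into contiguous batches of equal time length T_b and take T_b
  times the sample variance of the batch means.

Confidence intervals use the normal quantile, per the CLT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VarianceEstimate",
    "MSEResult",
    "ergodic_average",
    "ensemble_sigma2",
    "batch_means_sigma2",
    "mse",
    "confidence_interval",
]


@dataclass
class VarianceEstimate:
    """Point estimate of π(f) with asymptotic-variance estimate and CI."""

    estimate: float
    sigma2: float
    ci_low: float
    ci_high: float
    method: str
    T: float
    n_units: int              # replicas (ensemble) or batches (batch means)
    sigma2_se: float = np.nan  # ~ sigma2 * sqrt(2/(n_units - 1))


@dataclass
class MSEResult:
    mse: float
    relative: bool
    n_replicas: int
    diverged_fraction: float


def ergodic_average(series: np.ndarray, dt: Optional[float] = None,
                    burn_in: int = 0) -> float:
    """Mean of the post-burn-in series (Riemann approximation of π_T(f))."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    tail = series[burn_in:]
    if tail.size == 0:
        raise ValueError("no samples remain after burn-in")
    return float(tail.mean())


def confidence_interval(estimate: float, sigma2: float, T: float,
                        level: float = 0.95) -> tuple:
    """Normal-theory interval estimate ∓ z_level √(σ²/T)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if sigma2 < 0 or T <= 0:
        raise ValueError("need sigma2 >= 0 and T > 0")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(sigma2 / T)
    return (estimate - half, estimate + half)


def ensemble_sigma2(replica_estimates: Sequence[float], T: float,
                    level: float = 0.95) -> VarianceEstimate:
    """σ̂² = T · Var(π_T(f) across replicas); CLT interval for the mean.

    Replicas flagged as diverged (NaN) are dropped before estimating; at
    least two finite replicas are required.
    """
    est = np.asarray(replica_estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size < 2:
        raise ValueError("ensemble estimator needs at least 2 finite replicas")
    mean = float(est.mean())
    sigma2 = float(T * est.var(ddof=1))
    # SE of the cross-replica mean: sqrt(sigma2 / (T R))
    lo, hi = confidence_interval(mean, sigma2 / est.size, T, level)
    return VarianceEstimate(estimate=mean, sigma2=sigma2, ci_low=lo,
                            ci_high=hi, method="ensemble", T=float(T),
                            n_units=int(est.size),
                            sigma2_se=sigma2 * np.sqrt(2.0 / (est.size - 1)))


def batch_means_sigma2(series: np.ndarray, dt: float, n_batches: int = 30,
                       burn_in: int = 0,
                       level: float = 0.95) -> VarianceEstimate:
    """Batch-means σ̂² from one trajectory.

    The post-burn-in series is cut into ``n_batches`` contiguous batches
    of equal length (trailing remainder discarded); σ̂² = T_b · Var(batch
    means) with T_b the batch time length.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    series = np.asarray(series, dtype=float)[burn_in:]
    if series.size < 2 * n_batches:
        raise ValueError("series too short for the requested batch count")
    m = series.size // n_batches
    used = series[: m * n_batches].reshape(n_batches, m)
    means = used.mean(axis=1)
    Tb = m * dt
    T = m * n_batches * dt
    sigma2 = float(Tb * means.var(ddof=1))
    mean = float(used.mean())
    lo, hi = confidence_interval(mean, sigma2, T, level)
    return VarianceEstimate(estimate=mean, sigma2=sigma2, ci_low=lo,
                            ci_high=hi, method="batch_means", T=T,
                            n_units=n_batches,
                            sigma2_se=sigma2 * np.sqrt(2.0 / (n_batches - 1)))


def mse(estimates: Sequence[float], reference: float,
        relative: bool = False) -> MSEResult:
    """Mean squared error of replica estimates about a reference value.

    Diverged replicas (NaN/inf) are excluded and reported through
    ``diverged_fraction``; with ``relative`` the MSE is divided by
    reference².
    """
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    if relative and reference == 0.0:
        raise ValueError("relative MSE undefined for zero reference")
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    finite = np.isfinite(est)
    frac_div = float(1.0 - finite.mean())
    good = est[finite]
    if good.size == 0:
        value = np.nan
    else:
        value = float(np.mean((good - reference) ** 2))
        if relative:
            value /= reference**2
    return MSEResult(mse=value, relative=relative, n_replicas=int(est.size),
                     diverged_fraction=frac_div)
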