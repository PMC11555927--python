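"""Bootstrap confidence intervals for ATC ratio statistics.

Pairs (t, xΔ_t, yΔ_t) are resampled i.i.d. with replacement (serial
correlation is deliberately ignored; a block bootstrap is a possible
extension, not implemented).  Three interval constructions are offered:

percentile
    [q_{α/2}, q_{1−α/2}] of the bootstrap distribution of the statistic.
basic
    [2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2}], clipped to [0, 1].
bca
    Bias-corrected and accelerated: the percentile levels are shifted by
    a bias constant z0 (from the fraction of bootstrap values below the
    point estimate, counting ties half) and an acceleration constant
    estimated from the leave-one-out jackknife skewness.

Resamples on which the statistic is undefined (empty denominator, e.g.
every resampled pair excluded) are discarded and counted.  When the
statistic is one of the ratio estimators from :mod:`atckit.measures`
(anything exposing ``indicators``), resampling reduces to index sums of
two 0/1 vectors and is fully vectorized; arbitrary callables
``statistic(x_delta, y_delta) -> float`` are evaluated per resample on
the identical resample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import ndtr, ndtri

from .changes import PairedChangeSeries
from .measures import (
    NO_EXCLUSION,
    ATCEstimate,
    ATCStatistic,
    ExclusionArea,
    UndefinedEstimateError,
    _estimate,
)

__all__ = [
    "BootstrapSpec",
    "ConfidenceInterval",
    "bootstrap_ci",
    "bootstrap_intervals",
    "estimate_with_ci",
]

METHODS = ("percentile", "basic", "bca")


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling configuration.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed
    makes the interval bit-reproducible.
    """

    method: str = "bca"
    level: float = 0.9
    n_resamples: int = 2000
    seed: int | np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be at least 100")


@dataclass(frozen=True)
class ConfidenceInterval:
    low: float
    high: float
    level: float
    method: str
    n_discarded: int = 0
    degenerate: bool = False
    ordering_ok: bool = True


def _resample_thetas(
    x: np.ndarray,
    y: np.ndarray,
    statistic: Callable,
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Bootstrap distribution of the statistic; returns (values, n_discarded)."""
    n = x.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    if hasattr(statistic, "indicators"):
        num, den = statistic.indicators(x, y)
        num = num.astype(np.float64)
        den = den.astype(np.float64)
        num_s = num[idx].sum(axis=1)
        den_s = den[idx].sum(axis=1)
        valid = den_s > 0
        return num_s[valid] / den_s[valid], int(n_resamples - valid.sum())
    values, discarded = [], 0
    for row in idx:
        try:
            values.append(statistic(x[row], y[row]))
        except UndefinedEstimateError:
            discarded += 1
    return np.asarray(values, dtype=float), discarded


def _jackknife(x: np.ndarray, y: np.ndarray, statistic: Callable) -> np.ndarray:
    """Leave-one-out statistic values (undefined ones dropped)."""
    n = x.size
    if hasattr(statistic, "indicators"):
        num, den = statistic.indicators(x, y)
        num = num.astype(np.float64)
        den = den.astype(np.float64)
        num_loo = num.sum() - num
        den_loo = den.sum() - den
        ok = den_loo > 0
        return num_loo[ok] / den_loo[ok]
    values = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            values.append(statistic(x[mask], y[mask]))
        except UndefinedEstimateError:
            pass
        mask[i] = True
    return np.asarray(values, dtype=float)


def _percentile(thetas: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(thetas, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _interval(
    method: str,
    thetas: np.ndarray,
    theta_hat: float,
    jack: np.ndarray | None,
    level: float,
    n_discarded: int,
) -> ConfidenceInterval:
    if thetas.size == 0:
        raise UndefinedEstimateError("statistic undefined on every resample")
    if np.ptp(thetas) == 0.0 and (jack is None or jack.size == 0 or np.ptp(jack) == 0.0):
        # Degenerate sample: the bootstrap distribution carries no spread.
        return ConfidenceInterval(
            theta_hat, theta_hat, level, method, n_discarded, degenerate=True
        )

    if method == "percentile":
        lo, hi = _percentile(thetas, level)
        return ConfidenceInterval(lo, hi, level, method, n_discarded)

    if method == "basic":
        qlo, qhi = _percentile(thetas, level)
        lo = float(np.clip(2.0 * theta_hat - qhi, 0.0, 1.0))
        hi = float(np.clip(2.0 * theta_hat - qlo, 0.0, 1.0))
        ordering_ok = lo <= theta_hat <= hi
        return ConfidenceInterval(
            lo, hi, level, method, n_discarded, ordering_ok=ordering_ok
        )

    # BCa
    assert jack is not None
    centered = jack.mean() - jack
    denom = 6.0 * (centered**2).sum() ** 1.5
    if denom == 0.0:
        # Zero jackknife variance: acceleration undefined, fall back to
        # percentile quantiles and flag the degeneracy.
        lo, hi = _percentile(thetas, level)
        return ConfidenceInterval(lo, hi, level, method, n_discarded, degenerate=True)
    accel = (centered**3).sum() / denom
    n_boot = thetas.size
    frac_below = (
        (thetas < theta_hat).sum() + 0.5 * (thetas == theta_hat).sum()
    ) / n_boot
    frac_below = min(max(frac_below, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = ndtri(frac_below)
    alpha = 1.0 - level
    out = []
    for z_alpha in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        out.append(float(np.quantile(thetas, ndtr(adj))))
    return ConfidenceInterval(out[0], out[1], level, "bca", n_discarded)


def bootstrap_intervals(
    pairs: PairedChangeSeries,
    statistic: Callable,
    spec: BootstrapSpec,
    methods: tuple[str, ...] | None = None,
) -> dict[str, ConfidenceInterval]:
    """Intervals for several methods from one shared set of resamples.

    Sharing the bootstrap distribution makes percentile/basic/BCa
    directly comparable and halves the cost of method-comparison studies.
    """
    methods = methods if methods is not None else (spec.method,)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    x, y = pairs.x_delta, pairs.y_delta
    theta_hat = float(statistic(x, y))  # raises if undefined on the full sample
    rng = (
        spec.seed
        if isinstance(spec.seed, np.random.Generator)
        else np.random.default_rng(spec.seed)
    )
    thetas, n_discarded = _resample_thetas(x, y, statistic, spec.n_resamples, rng)
    jack = _jackknife(x, y, statistic) if "bca" in methods else None
    return {
        m: _interval(m, thetas, theta_hat, jack, spec.level, n_discarded)
        for m in methods
    }


def bootstrap_ci(
    pairs: PairedChangeSeries, statistic: Callable, spec: BootstrapSpec
) -> ConfidenceInterval:
    """Confidence interval for one statistic under one method."""
    return bootstrap_intervals(pairs, statistic, spec)[spec.method]


def estimate_with_ci(
    pairs: PairedChangeSeries,
    direction: str | None = None,
    exclusion: ExclusionArea = NO_EXCLUSION,
    spec: BootstrapSpec = BootstrapSpec(),
) -> ATCEstimate:
    """ATC ratio estimate with an attached bootstrap confidence interval."""
    statistic = ATCStatistic(direction=direction, exclusion=exclusion)
    estimate = _estimate(pairs, statistic)
    ci = bootstrap_ci(pairs, statistic, spec)
    return replace(estimate, ci=ci)
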