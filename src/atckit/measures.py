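"""ATC ratio estimators with optional exclusion areas.

The ATC ratio μ estimates P(XΔ·YΔ > 0), the probability that a
prediction gets the direction of change right; it is the fraction of
points in the concordant quadrants of a four-quadrant plot.  The signed
variants μ⁺ and μ⁻ condition on the predicted change being positive or
negative.  An exclusion area around the origin drops pairs whose
quadrant assignment is likely noise-driven (small changes); its
boundary is inclusive, so a point exactly on the boundary is excluded.

A pair with ``xΔ·yΔ == 0`` is never concordant (the sign condition is
strict) but still counts in the denominator.  Real data contain exact
zero changes, so this convention matters: a method that predicts "no
change" is scored as having missed the direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .changes import PairedChangeSeries

__all__ = [
    "UndefinedEstimateError",
    "ExclusionArea",
    "NO_EXCLUSION",
    "in_exclusion",
    "ATCStatistic",
    "ATCEstimate",
    "atc_ratio",
    "atc_ratio_signed",
    "rolling_atc",
    "exclusion_from_quantile",
    "atc_over_exclusion_sizes",
]

SHAPES = ("none", "rectangle", "x_band", "y_band", "cross")
DIRECTIONS = (None, "positive", "negative")


class UndefinedEstimateError(ValueError):
    """No pairs remain in the denominator of a ratio estimator."""


@dataclass(frozen=True)
class ExclusionArea:
    """Region around the origin whose points are dropped from estimation.

    Shapes: ``rectangle`` (small in both components), ``x_band`` /
    ``y_band`` (small in the predicted / true component), ``cross``
    (small in at least one component), and ``none`` (empty set).
    Thresholds apply to absolute values and boundaries are inclusive.
    """

    shape: str = "none"
    eps_x: float = 0.0
    eps_y: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.eps_x < 0 or self.eps_y < 0:
            raise ValueError("exclusion thresholds must be nonnegative")

    def contains(self, y_delta, x_delta) -> np.ndarray:
        """Boolean membership of points ``(yΔ, xΔ)`` in the area."""
        yd = np.abs(np.asarray(y_delta, dtype=float))
        xd = np.abs(np.asarray(x_delta, dtype=float))
        if self.shape == "none":
            return np.zeros(np.broadcast(yd, xd).shape, dtype=bool)
        if self.shape == "rectangle":
            return (xd <= self.eps_x) & (yd <= self.eps_y)
        if self.shape == "x_band":
            return xd <= self.eps_x
        if self.shape == "y_band":
            return yd <= self.eps_y
        return (xd <= self.eps_x) | (yd <= self.eps_y)  # cross


NO_EXCLUSION = ExclusionArea()


def in_exclusion(area: ExclusionArea, y_delta, x_delta):
    """Membership predicate; scalar in, scalar out."""
    out = area.contains(y_delta, x_delta)
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ATCStatistic:
    """A ratio estimator as a reusable closure over (xΔ, yΔ) arrays.

    ``direction=None`` gives the overall ATC ratio; ``"positive"`` /
    ``"negative"`` restrict the denominator to the sign of the predicted
    change.  The exclusion area is fixed at construction, so resampling
    (bootstrap) keeps the estimand unchanged.  ``indicators`` exposes the
    per-pair numerator/denominator memberships, which lets the bootstrap
    recompute the statistic on resamples via index sums alone.
    """

    direction: str | None = None
    exclusion: ExclusionArea = NO_EXCLUSION

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    def indicators(self, x_delta, y_delta) -> tuple[np.ndarray, np.ndarray]:
        xd = np.asarray(x_delta, dtype=float)
        yd = np.asarray(y_delta, dtype=float)
        den = ~self.exclusion.contains(yd, xd)
        if self.direction == "positive":
            den = den & (xd > 0)
        elif self.direction == "negative":
            den = den & (xd < 0)
        num = den & (xd * yd > 0)
        return num, den

    def __call__(self, x_delta, y_delta) -> float:
        num, den = self.indicators(x_delta, y_delta)
        d = int(den.sum())
        if d == 0:
            raise UndefinedEstimateError(
                "no pairs in the denominator (all excluded or wrong sign)"
            )
        return float(num.sum()) / d


@dataclass(frozen=True)
class ATCEstimate:
    """An estimated ratio in [0, 1] with the pair counts behind it."""

    value: float
    n_used: int
    n_total: int
    ci: Any | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("estimate must lie in [0, 1]")
        if self.n_used > self.n_total:
            raise ValueError("n_used cannot exceed n_total")


def _estimate(pairs: PairedChangeSeries, statistic: ATCStatistic) -> ATCEstimate:
    num, den = statistic.indicators(pairs.x_delta, pairs.y_delta)
    d = int(den.sum())
    if d == 0:
        raise UndefinedEstimateError(
            "no pairs in the denominator (all excluded or wrong sign)"
        )
    return ATCEstimate(value=float(num.sum()) / d, n_used=d, n_total=len(pairs))


def atc_ratio(
    pairs: PairedChangeSeries, exclusion: ExclusionArea = NO_EXCLUSION
) -> ATCEstimate:
    """Overall ATC ratio μ: concordant pairs over considered pairs."""
    return _estimate(pairs, ATCStatistic(exclusion=exclusion))


def atc_ratio_signed(
    pairs: PairedChangeSeries,
    direction: str,
    exclusion: ExclusionArea = NO_EXCLUSION,
) -> ATCEstimate:
    """Signed ATC ratio μ⁺ or μ⁻ (denominator restricted by sign of xΔ)."""
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    return _estimate(pairs, ATCStatistic(direction=direction, exclusion=exclusion))


def rolling_atc(pairs: PairedChangeSeries, window: int) -> pd.Series:
    """Backward-looking rolling ATC ratio over consecutive pairs.

    The value reported at time ``t`` is the concordance fraction over the
    window of the ``window`` most recent pairs ending at ``t``; it is
    emitted for every time where the full window exists.  Windows are
    indexed over the pair sequence, so gaps in calendar time compress.
    """
    n = len(pairs)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    conc = (pairs.x_delta * pairs.y_delta > 0).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(conc)])
    values = (csum[window:] - csum[:-window]) / window
    return pd.Series(values, index=pairs.times[window - 1 :], name="rolling_atc")


def exclusion_from_quantile(
    pairs: PairedChangeSeries, q: float, shape: str = "rectangle"
) -> ExclusionArea:
    """Size an exclusion area from the empirical q-quantile of |changes|.

    ``eps_x`` and ``eps_y`` are the q-quantiles of the absolute predicted
    and true changes; with the default rectangle a point is excluded iff
    *both* components fall at or below their quantile (so points large in
    one dimension stay in the assessment).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    if len(pairs) == 0:
        raise ValueError("cannot size an exclusion area from an empty series")
    return ExclusionArea(
        shape=shape,
        eps_x=float(np.quantile(np.abs(pairs.x_delta), q)),
        eps_y=float(np.quantile(np.abs(pairs.y_delta), q)),
    )


def atc_over_exclusion_sizes(
    pairs: PairedChangeSeries,
    sizes,
    shape: str = "rectangle",
    size_mode: str = "scale",
) -> pd.DataFrame:
    """ATC ratio across a grid of exclusion-area sizes.

    ``size_mode="scale"`` treats each size as the threshold itself
    (``eps_x = eps_y = size``); ``"quantile"`` sizes via
    :func:`exclusion_from_quantile`.  Size 0 means no exclusion.  Sizes
    at which the estimate is undefined produce NaN gaps.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("size grid must be nonempty")
    if size_mode not in ("scale", "quantile"):
        raise ValueError("size_mode must be 'scale' or 'quantile'")
    rows = []
    for size in sizes:
        if size == 0:
            area = NO_EXCLUSION
        elif size_mode == "scale":
            area = ExclusionArea(shape=shape, eps_x=size, eps_y=size)
        else:
            area = exclusion_from_quantile(pairs, size, shape=shape)
        try:
            est = atc_ratio(pairs, area)
            rows.append((size, area.eps_x, area.eps_y, est.value, est.n_used))
        except UndefinedEstimateError:
            rows.append((size, area.eps_x, area.eps_y, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["size", "eps_x", "eps_y", "value", "n_used"]
    )
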