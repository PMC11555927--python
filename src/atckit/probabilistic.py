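"""Probabilistic ATC: probabilities of increase, Brier score, reliability.

A probabilistic nowcast/forecast issues a predictive distribution for
the target value; the implied probability of a *positive change* over
horizon l is p_t = 1 − F(y_{t−l}) where F is the predictive CDF (for
nowcasts F_{t|t}, for forecasts F_{t|t−l}).  Predictions given as
quantile sets are handled through a piecewise-linear CDF (uniform mass
within each quantile interval, with the tail mass spread uniformly over
an interval the width of the nearest inner one); predictions for which
the reference value itself is uncertain are handled by Monte-Carlo
sampling from the two predictive distributions.

The predicted probabilities p_t are scored against the observed
increase indicators z_t = 1{yΔ_t > 0} with the Brier score (mean squared
difference; 0.25 for constant 0.5 guessing, 0 for perfect certainty)
and inspected with reliability tables/diagrams (observed increase
frequency per bin of predicted probability; calibrated forecasts lie on
the diagonal).

Exact-zero observed changes count as "no increase" (the definition is
strict); their count is exposed so users can assess sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .changes import ChangeSeries

__all__ = [
    "InvalidCDFError",
    "QuantileSet",
    "ProbabilisticSeries",
    "prob_increase_from_cdf",
    "prob_increase_from_quantiles",
    "quantile_sampler",
    "prob_positive_change_two_dists",
    "increase_indicators",
    "zero_change_count",
    "brier_score",
    "reliability_table",
]


class InvalidCDFError(ValueError):
    """A CDF evaluator returned a value outside [0, 1]."""


@dataclass(frozen=True)
class QuantileSet:
    """Predictive quantiles q_p at strictly increasing levels p in (0, 1)."""

    levels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if levels.ndim != 1 or levels.shape != values.shape:
            raise ValueError("levels and values must be 1-d arrays of equal length")
        if levels.size < 2:
            raise ValueError("at least two quantile levels are required")
        if levels.min() <= 0.0 or levels.max() >= 1.0:
            raise ValueError("levels must lie strictly inside (0, 1)")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(np.diff(values) < 0):
            raise ValueError("quantile values must be nondecreasing")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "values", values)

    def cdf_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Knots of the piecewise-linear CDF, with tail extension.

        Below the lowest (above the highest) quantile, the remaining
        mass is spread uniformly over an interval of the same width as
        the nearest inner interval.  Duplicate knot positions (atoms)
        collapse to the largest level — the CDF is right-continuous and
        an atom carries its full mass at the point.
        """
        q, p = self.values, self.levels
        widths = np.diff(q)
        positive = widths[widths > 0]
        if positive.size == 0:
            # All quantiles equal: a point mass at q[0].
            return np.array([q[0]]), np.array([1.0])
        # A zero-width nearest interval (an atom at the extreme) would make
        # the tail rule degenerate; extend by the nearest positive width.
        w_lo = positive[0]
        w_hi = positive[-1]
        knots_q = np.concatenate([[q[0] - w_lo], q, [q[-1] + w_hi]])
        knots_p = np.concatenate([[0.0], p, [1.0]])
        # Keep the last (largest-level) entry for each repeated position.
        uniq_q, last_idx = np.unique(knots_q[::-1], return_index=True)
        uniq_p = knots_p[::-1][last_idx]
        return uniq_q, uniq_p


def prob_increase_from_cdf(F: Callable[[float], float], y_prev: float) -> float:
    """p = 1 − F(y_prev): predicted probability of a positive change."""
    value = float(F(y_prev))
    if not 0.0 <= value <= 1.0:
        raise InvalidCDFError(f"F(y_prev) = {value} is outside [0, 1]")
    return 1.0 - value


def prob_increase_from_quantiles(qs: QuantileSet, y_prev: float) -> float:
    """Probability of increase from a quantile set.

    Builds the piecewise-linear CDF through (q_p, p) with uniform tail
    extension and returns p = 1 − F(y_prev).  If y_prev falls on an atom
    (two or more equal quantile values), the upper level applies and a
    warning is issued.
    """
    q = qs.values
    atoms = q[:-1][np.diff(q) == 0.0]
    if np.any(atoms == y_prev):
        warnings.warn(
            "reference value coincides with a quantile mass point; the upper "
            "level is used",
            stacklevel=2,
        )
    knots_q, knots_p = qs.cdf_knots()
    p_neg = float(np.interp(y_prev, knots_q, knots_p, left=0.0, right=1.0))
    return 1.0 - p_neg


def quantile_sampler(qs: QuantileSet) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Sampler drawing from the piecewise-linear CDF by inverse transform."""
    knots_q, knots_p = qs.cdf_knots()

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return np.interp(rng.random(n), knots_p, knots_q)

    return sample


def prob_positive_change_two_dists(
    sampler_now: Callable[[int, np.random.Generator], np.ndarray],
    sampler_prev: Callable[[int, np.random.Generator], np.ndarray],
    n_samples: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo probability of a positive change between two predictive laws.

    Draws ``n_samples`` independent pairs (the two distributions are
    assumed independent; pass a joint sampler as ``sampler_now`` with a
    degenerate ``sampler_prev`` to model dependence) and returns the
    fraction with a strictly positive difference.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    now = np.asarray(sampler_now(n_samples, rng), dtype=float)
    prev = np.asarray(sampler_prev(n_samples, rng), dtype=float)
    return float(np.mean(now - prev > 0.0))


def increase_indicators(y_delta: ChangeSeries) -> pd.Series:
    """z_t = 1{yΔ_t > 0} on the times where yΔ is defined (zeros give 0)."""
    z = (y_delta.deltas > 0.0).astype(np.int64)
    return pd.Series(z, index=y_delta.times, name="z")


def zero_change_count(y_delta: ChangeSeries) -> int:
    """Number of exact-zero observed changes (scored as non-increases)."""
    return int((y_delta.deltas == 0.0).sum())


@dataclass(frozen=True)
class ProbabilisticSeries:
    """Aligned predicted increase probabilities and observed indicators."""

    times: np.ndarray
    p: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        p = np.asarray(self.p, dtype=float)
        z = np.asarray(self.z, dtype=np.int64)
        if not (times.shape == p.shape == z.shape) or times.ndim != 1:
            raise ValueError("times, p, z must be 1-d arrays of equal length")
        if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("indicators must be 0 or 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "z", z)

    @classmethod
    def from_series(cls, p: pd.Series, z: pd.Series) -> "ProbabilisticSeries":
        """Align on common times, excluding missing values on either side."""
        joined = pd.concat({"p": p, "z": z}, axis=1, join="inner").dropna()
        return cls(
            joined.index.to_numpy(), joined["p"].to_numpy(), joined["z"].to_numpy()
        )

    def __len__(self) -> int:
        return int(self.times.size)


def brier_score(series: ProbabilisticSeries) -> float:
    """Mean squared difference between p_t and z_t over scored times.

    Missing times are already excluded by construction; the mean is over
    the non-missing scored times.  Lower is better; 0.25 is the constant
    0.5 benchmark.
    """
    if len(series) == 0:
        raise ValueError("no scored times; Brier score is undefined")
    return float(np.mean((series.p - series.z) ** 2))


def reliability_table(
    series: ProbabilisticSeries, n_bins: int = 10, binning: str = "quantile"
) -> pd.DataFrame:
    """Binned calibration table behind the reliability diagram.

    ``binning="quantile"`` (default) chooses bin edges at empirical
    quantiles of the predicted probabilities, keeping ties in one bin —
    bins may merge (with a warning) when there are few distinct values.
    ``"equal_width"`` partitions [0, 1] evenly; empty bins are emitted
    with count 0 and NaN frequency.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if binning not in ("quantile", "equal_width"):
        raise ValueError("binning must be 'quantile' or 'equal_width'")
    if len(series) == 0:
        raise ValueError("empty series")
    p, z = series.p, series.z
    if binning == "quantile":
        edges = np.unique(np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1)))
        if edges.size - 1 < n_bins:
            warnings.warn(
                f"only {max(edges.size - 1, 1)} distinct quantile bins available; "
                "bins merged",
                stacklevel=2,
            )
        if edges.size < 2:  # constant predictions: a single bin
            edges = np.array([edges[0], edges[0]])
    else:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    # Assign by right-open intervals so ties at an edge share a bin.
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        count = int(sel.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_p": float(p[sel].mean()) if count else np.nan,
                "obs_freq": float(z[sel].mean()) if count else np.nan,
                "count": count,
            }
        )
    return pd.DataFrame(rows)
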