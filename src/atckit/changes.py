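"""Change series for measurements, nowcasts, and forecasts.

The ability to track changes (ATC) is assessed on *paired changes*: the
true change of the quantity of interest over a horizon ``l``,
``yΔ_t = y_t − y_{t−l}``, against the change predicted by a measurement
device, nowcast, or forecast.  How the predicted change is computed
depends on the application:

measurement
    ``xΔ_t = x_t − x_{t−l}`` — purely from the test method, never mixing
    in the gold standard, so that the consistency of the two methods'
    changes is what is being assessed.
nowcast
    ``xΔ_t = x_{t|t} − y_{t−l}`` when the true value at ``t−l`` is
    already known at issue time ``t`` (the nowcaster knew it too),
    otherwise ``xΔ_t = x_{t|t} − x_{t−l|t}`` using the revised nowcast
    for ``t−l`` issued at ``t``.
forecast
    ``xΔ_t = x_{t|t−l} − y_{t−l}``; if the truth at ``t−l`` was not yet
    known at issue time, the same fallback mechanism applies with the
    nowcast-style value ``x_{t−l|t−l}``.

Time is an abstract integer index; calendar parsing lives in
:mod:`atckit.io`.  Missing data are represented as absent entries, never
as sentinel values: one missing raw value at time ``t`` removes exactly
the two change entries ``t`` and ``t+l`` (where in range), and a pair is
dropped from the aligned series as soon as either side is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "InvalidHorizonError",
    "ModeMismatchError",
    "ValueSeries",
    "PredictionPanel",
    "ChangeSeries",
    "PairedChangeSeries",
    "reporting_delay_predicate",
    "true_changes",
    "predicted_changes_measurement",
    "predicted_changes_nowcast",
    "predicted_changes_forecast",
    "align_pairs",
]


class InvalidHorizonError(ValueError):
    """The change horizon is incompatible with the series."""


class ModeMismatchError(ValueError):
    """The prediction panel does not match the requested mode."""


TruthKnown = Callable[[int, int], bool]


def reporting_delay_predicate(delay: int = 0) -> TruthKnown:
    """Truth-availability predicate with a fixed reporting delay.

    Returns a predicate ``known(s, t)`` that is true iff the true value
    for time ``s`` has been reported by time ``t``, i.e. ``s <= t - delay``.
    The default ``delay=0`` means the truth is known as soon as its time
    has passed (whenever the value is present at all).
    """

    def known(s: int, t: int) -> bool:
        return s <= t - delay

    return known


def _as_1d(a, dtype) -> np.ndarray:
    out = np.asarray(a, dtype=dtype)
    if out.ndim != 1:
        raise ValueError("expected a one-dimensional array")
    return out


@dataclass(frozen=True)
class ValueSeries:
    """A time series of observed values on an integer time grid.

    Missing values may be passed as NaN/None; they are dropped on
    construction so that the stored entries are exactly the *present*
    ones.  ``times`` must be unique and strictly increasing.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = _as_1d(self.times, np.int64)
        values = _as_1d(self.values, float)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        keep = np.isfinite(values)
        times, values = times[keep], values[keep]
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be unique and strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_values(cls, values) -> "ValueSeries":
        """Build a series on times ``0..len(values)-1``; NaNs are missing."""
        values = np.asarray(values, dtype=float)
        return cls(np.arange(values.size), values)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.times.tolist(), self.values.tolist()))

    @property
    def t_max(self) -> int:
        if self.times.size == 0:
            raise ValueError("empty series")
        return int(self.times[-1])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PredictionPanel:
    """Predictions ``x_{t|τ}`` indexed by target time ``t`` and issue time ``τ``.

    For measurements the issue time equals the target time.  At most one
    record per ``(t, τ)`` is allowed and both indices are nonnegative.
    """

    target_times: np.ndarray
    issue_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = _as_1d(self.target_times, np.int64)
        tau = _as_1d(self.issue_times, np.int64)
        v = _as_1d(self.values, float)
        if not (t.shape == tau.shape == v.shape):
            raise ValueError("panel columns must have equal length")
        if t.size and (t.min() < 0 or tau.min() < 0):
            raise ValueError("target and issue times must be nonnegative")
        keep = np.isfinite(v)
        t, tau, v = t[keep], tau[keep], v[keep]
        pairs = set(zip(t.tolist(), tau.tolist()))
        if len(pairs) != t.size:
            raise ValueError("duplicate (target_time, issue_time) records")
        object.__setattr__(self, "target_times", t)
        object.__setattr__(self, "issue_times", tau)
        object.__setattr__(self, "values", v)

    @classmethod
    def measurement(cls, series: ValueSeries) -> "PredictionPanel":
        """Wrap a plain measurement series (issue time = target time)."""
        return cls(series.times, series.times, series.values)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionPanel":
        if {"target_time", "issue_time", "value"} <= set(df.columns):
            return cls(
                df["target_time"].to_numpy(),
                df["issue_time"].to_numpy(),
                df["value"].to_numpy(),
            )
        if {"time", "value"} <= set(df.columns):
            return cls.measurement(
                ValueSeries(df["time"].to_numpy(), df["value"].to_numpy())
            )
        raise ValueError(
            "expected columns (target_time, issue_time, value) or (time, value)"
        )

    def as_dict(self) -> dict[tuple[int, int], float]:
        return dict(
            zip(
                zip(self.target_times.tolist(), self.issue_times.tolist()),
                self.values.tolist(),
            )
        )

    @property
    def is_measurement(self) -> bool:
        return bool(np.all(self.target_times == self.issue_times))

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ChangeSeries:
    """Changes over a fixed horizon; absent times are undefined entries."""

    horizon: int
    times: np.ndarray
    deltas: np.ndarray

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise InvalidHorizonError("horizon must be a positive integer")
        times = _as_1d(self.times, np.int64)
        deltas = _as_1d(self.deltas, float)
        if times.shape != deltas.shape:
            raise ValueError("times and deltas must have equal length")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("times must be unique and strictly increasing")
            if times[0] < self.horizon:
                raise ValueError("change times must satisfy t >= horizon")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "deltas", deltas)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.times.tolist(), self.deltas.tolist()))

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PairedChangeSeries:
    """Aligned (t, xΔ_t, yΔ_t) triples at a common horizon, no missing entries."""

    horizon: int
    times: np.ndarray
    x_delta: np.ndarray
    y_delta: np.ndarray
    n_dropped: int = field(default=0, compare=False)
    meta: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        times = _as_1d(self.times, np.int64)
        xd = _as_1d(self.x_delta, float)
        yd = _as_1d(self.y_delta, float)
        if not (times.shape == xd.shape == yd.shape):
            raise ValueError("times, x_delta, y_delta must have equal length")
        if not (np.isfinite(xd).all() and np.isfinite(yd).all()):
            raise ValueError("paired changes must be fully defined")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be unique and strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x_delta", xd)
        object.__setattr__(self, "y_delta", yd)

    @classmethod
    def from_arrays(cls, x_delta, y_delta, horizon: int = 1) -> "PairedChangeSeries":
        x_delta = np.asarray(x_delta, dtype=float)
        times = np.arange(horizon, horizon + x_delta.size)
        return cls(horizon, times, x_delta, y_delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x_delta": self.x_delta, "y_delta": self.y_delta}
        )

    def __len__(self) -> int:
        return int(self.times.size)


def _check_horizon(horizon: int, t_max: int) -> None:
    if not isinstance(horizon, (int, np.integer)) or horizon < 1:
        raise InvalidHorizonError(f"horizon must be a positive integer, got {horizon}")
    if horizon > t_max:
        raise InvalidHorizonError(
            f"horizon {horizon} exceeds the last time index {t_max}"
        )


def true_changes(y: ValueSeries, horizon: int) -> ChangeSeries:
    """True change series ``yΔ_t = y_t − y_{t−l}`` for ``t = l..T``.

    A time ``t`` is present iff both ``y_t`` and ``y_{t−l}`` are present;
    one missing raw value therefore removes the two differences it enters.
    """
    _check_horizon(horizon, y.t_max)
    vals = y.as_dict()
    times, deltas = [], []
    for t in y.times.tolist():
        if t >= horizon and (t - horizon) in vals:
            times.append(t)
            deltas.append(vals[t] - vals[t - horizon])
    return ChangeSeries(horizon, np.asarray(times, dtype=np.int64), np.asarray(deltas))


def predicted_changes_measurement(x: PredictionPanel, horizon: int) -> ChangeSeries:
    """Measurement-mode predicted changes ``xΔ_t = x_t − x_{t−l}``.

    Uses only the test method's own values; the gold standard never
    enters, even where available.
    """
    if not x.is_measurement:
        raise ModeMismatchError(
            "panel contains nowcast/forecast-style records; measurement mode "
            "requires issue_time == target_time throughout"
        )
    series = ValueSeries(x.target_times, x.values)
    return true_changes(series, horizon)


def predicted_changes_nowcast(
    x: PredictionPanel,
    y: ValueSeries,
    horizon: int,
    truth_known: TruthKnown | None = None,
) -> ChangeSeries:
    """Nowcast-mode predicted changes.

    ``xΔ_t = x_{t|t} − y_{t−l}`` when the truth at ``t−l`` is known at
    time ``t`` (per ``truth_known``) and present; otherwise
    ``x_{t|t} − x_{t−l|t}``.  Entries with no usable operand are absent.
    """
    if truth_known is None:
        truth_known = reporting_delay_predicate(0)
    panel = x.as_dict()
    truth = y.as_dict()
    _check_horizon(horizon, max(int(x.target_times.max(initial=0)), 1))
    times, deltas = [], []
    for t in sorted({int(t) for t in x.target_times}):
        if t < horizon or (t, t) not in panel:
            continue
        now = panel[(t, t)]
        s = t - horizon
        if truth_known(s, t) and s in truth:
            prev = truth[s]
        elif (s, t) in panel:
            prev = panel[(s, t)]
        else:
            continue
        times.append(t)
        deltas.append(now - prev)
    return ChangeSeries(horizon, np.asarray(times, dtype=np.int64), np.asarray(deltas))


def predicted_changes_forecast(
    x: PredictionPanel,
    y: ValueSeries,
    horizon: int,
    truth_known: TruthKnown | None = None,
) -> ChangeSeries:
    """Forecast-mode predicted changes ``xΔ_t = x_{t|t−l} − y_{t−l}``.

    If the truth at ``t−l`` was not yet known at issue time ``t−l`` (per
    ``truth_known``), the nowcast-style value ``x_{t−l|t−l}`` substitutes
    for it; entries with no usable operand are absent.
    """
    if truth_known is None:
        truth_known = reporting_delay_predicate(0)
    panel = x.as_dict()
    truth = y.as_dict()
    _check_horizon(horizon, max(int(x.target_times.max(initial=0)), 1))
    times, deltas = [], []
    for t in sorted({int(t) for t in x.target_times}):
        s = t - horizon
        if s < 0 or (t, s) not in panel:
            continue
        fc = panel[(t, s)]
        if truth_known(s, s) and s in truth:
            prev = truth[s]
        elif (s, s) in panel:
            prev = panel[(s, s)]
        else:
            continue
        times.append(t)
        deltas.append(fc - prev)
    return ChangeSeries(horizon, np.asarray(times, dtype=np.int64), np.asarray(deltas))


def align_pairs(x_delta: ChangeSeries, y_delta: ChangeSeries) -> PairedChangeSeries:
    """Intersect two change series on the times where both are defined.

    The returned series records, in ``n_dropped``, how many times were
    present on one side only (a pair is excluded even if its nowcast or
    forecast is available when the true change is not, and vice versa).
    """
    if x_delta.horizon != y_delta.horizon:
        raise InvalidHorizonError(
            f"horizon mismatch: {x_delta.horizon} vs {y_delta.horizon}"
        )
    xd, yd = x_delta.as_dict(), y_delta.as_dict()
    common = sorted(set(xd) & set(yd))
    n_dropped = (len(xd) - len(common)) + (len(yd) - len(common))
    times = np.asarray(common, dtype=np.int64)
    return PairedChangeSeries(
        x_delta.horizon,
        times,
        np.asarray([xd[t] for t in common]),
        np.asarray([yd[t] for t in common]),
        n_dropped=n_dropped,
    )
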