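"""CSV input/output for truth series, prediction panels, and quantile panels.

Time handling: the analysis operates on an abstract integer time index.
If a time column parses as integers it is used directly; otherwise it is
parsed as timestamps and mapped onto a regular integer grid whose step
is the greatest common divisor of the observed spacings — rows then land
on distinct grid points and gaps simply remain missing.  Timestamps that
do not fall on the grid raise an error rather than being interpolated.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .changes import PairedChangeSeries, PredictionPanel, ValueSeries
from .probabilistic import QuantileSet

__all__ = [
    "read_truth_csv",
    "read_prediction_csv",
    "read_pairs_csv",
    "write_pairs_csv",
    "read_quantile_csv",
]

_QUANTILE_COL = re.compile(r"^q_(0?\.\d+|1\.0*|0)$")


def _to_int_grid(col: pd.Series) -> np.ndarray:
    """Map a time column to integer indices (see module docstring)."""
    if pd.api.types.is_integer_dtype(col):
        return col.to_numpy(dtype=np.int64)
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        values = numeric.to_numpy()
        if not np.allclose(values, np.round(values)):
            raise ValueError("non-integer numeric time column")
        return np.round(values).astype(np.int64)
    stamps = pd.to_datetime(col).astype("int64").to_numpy()
    order = np.sort(np.unique(stamps))
    if order.size < 2:
        return np.zeros(stamps.size, dtype=np.int64)
    step = np.gcd.reduce(np.diff(order))
    offset = stamps - order[0]
    if np.any(offset % step):
        raise ValueError("timestamps do not fall on a regular grid")
    return (offset // step).astype(np.int64)


def read_truth_csv(path) -> ValueSeries:
    """Truth series from a CSV with columns ``time,value``."""
    df = pd.read_csv(path)
    if not {"time", "value"} <= set(df.columns):
        raise ValueError("truth CSV requires columns time,value")
    return ValueSeries(_to_int_grid(df["time"]), df["value"].to_numpy(dtype=float))


def read_prediction_csv(path) -> PredictionPanel:
    """Prediction panel from ``target_time,issue_time,value`` or ``time,value``."""
    df = pd.read_csv(path)
    if {"target_time", "issue_time", "value"} <= set(df.columns):
        return PredictionPanel(
            _to_int_grid(df["target_time"]),
            _to_int_grid(df["issue_time"]),
            df["value"].to_numpy(dtype=float),
        )
    if {"time", "value"} <= set(df.columns):
        return PredictionPanel.measurement(
            ValueSeries(_to_int_grid(df["time"]), df["value"].to_numpy(dtype=float))
        )
    raise ValueError(
        "prediction CSV requires columns target_time,issue_time,value "
        "or time,value"
    )


def write_pairs_csv(pairs: PairedChangeSeries, path) -> None:
    """Write aligned pairs as ``t,x_delta,y_delta`` (horizon in the name only)."""
    pairs.to_frame().to_csv(path, index=False)


def read_pairs_csv(path, horizon: int = 1) -> PairedChangeSeries:
    df = pd.read_csv(path)
    if not {"t", "x_delta", "y_delta"} <= set(df.columns):
        raise ValueError("pairs CSV requires columns t,x_delta,y_delta")
    return PairedChangeSeries(
        horizon,
        df["t"].to_numpy(dtype=np.int64),
        df["x_delta"].to_numpy(dtype=float),
        df["y_delta"].to_numpy(dtype=float),
    )


def read_quantile_csv(path) -> dict[tuple[int, int], QuantileSet]:
    """Quantile panel: ``target_time,issue_time,q_<level>,...`` columns.

    Levels are parsed from the headers (e.g. ``q_0.025``); one
    :class:`QuantileSet` per (target_time, issue_time) record.  Rows with
    any missing quantile are skipped.
    """
    df = pd.read_csv(path)
    if not {"target_time", "issue_time"} <= set(df.columns):
        raise ValueError("quantile CSV requires target_time and issue_time columns")
    qcols = [c for c in df.columns if _QUANTILE_COL.match(c)]
    if len(qcols) < 2:
        raise ValueError("quantile CSV requires at least two q_<level> columns")
    levels = np.array([float(c[2:]) for c in qcols])
    order = np.argsort(levels)
    levels = levels[order]
    qcols = [qcols[i] for i in order]
    target = _to_int_grid(df["target_time"])
    issue = _to_int_grid(df["issue_time"])
    out: dict[tuple[int, int], QuantileSet] = {}
    for i in range(len(df)):
        values = df.loc[df.index[i], qcols].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            continue
        out[(int(target[i]), int(issue[i]))] = QuantileSet(levels, values)
    return out
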