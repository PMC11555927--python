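"""Publication-style plots for ATC assessment.

All plots are pure functions of their inputs: fixed styling, no
timestamps, deterministic rendering.  Numeric assertions belong on the
computed tables and curves; these functions only draw them.  Each
function returns ``(fig, ax)`` and optionally writes to ``path``
(png/pdf/svg inferred from the suffix).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .changes import PairedChangeSeries
from .conditional import ConditionalATCCurve
from .measures import ExclusionArea

__all__ = [
    "four_quadrant_plot",
    "rolling_plot",
    "exclusion_sweep_plot",
    "conditional_plot",
    "reliability_plot",
]

_CONCORDANT = "#d9ead9"  # light green
_DISCORDANT = "#f4d7d7"  # light red
_FORMATS = (".png", ".pdf", ".svg")


def _finish(fig, path):
    if path is not None:
        path = Path(path)
        if path.suffix not in _FORMATS:
            raise ValueError(f"output format must be one of {_FORMATS}")
        fig.savefig(path, bbox_inches="tight")
    return fig


def _new_axes(ax):
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    return fig, ax


def four_quadrant_plot(
    pairs: PairedChangeSeries,
    exclusion: ExclusionArea | None = None,
    color_by_time: bool = False,
    path=None,
    ax=None,
):
    """True change on the x-axis, predicted change on the y-axis.

    The upper-right and lower-left quadrants (correct direction) are
    tinted green, the others red.  With ``color_by_time`` points fade
    from blue (early) to green (late).  An exclusion area, if given, is
    drawn as a hatched overlay.
    """
    if len(pairs) == 0:
        raise ValueError("cannot plot an empty paired series")
    fig, ax = _new_axes(ax)
    yd, xd = pairs.y_delta, pairs.x_delta
    lim_x = 1.1 * max(np.abs(yd).max(), 1e-9)
    lim_y = 1.1 * max(np.abs(xd).max(), 1e-9)
    for sx, sy, color in (
        (1, 1, _CONCORDANT),
        (-1, -1, _CONCORDANT),
        (1, -1, _DISCORDANT),
        (-1, 1, _DISCORDANT),
    ):
        ax.fill_between(
            [0, sx * lim_x], 0, sy * lim_y, color=color, zorder=0, linewidth=0
        )
    if exclusion is not None and exclusion.shape != "none":
        kw = dict(color="0.45", alpha=0.35, hatch="///", zorder=1, linewidth=0)
        ex, ey = exclusion.eps_x, exclusion.eps_y
        if exclusion.shape in ("rectangle",):
            ax.fill_between([-ey, ey], -ex, ex, **kw)
        if exclusion.shape in ("x_band", "cross"):
            ax.fill_between([-lim_x, lim_x], -ex, ex, **kw)
        if exclusion.shape in ("y_band", "cross"):
            ax.fill_between([-ey, ey], -lim_y, lim_y, **kw)
    if color_by_time:
        sc = ax.scatter(
            yd, xd, c=pairs.times, cmap="winter", s=12, zorder=2, edgecolors="none"
        )
        fig.colorbar(sc, ax=ax, label="time index t")
    else:
        ax.scatter(yd, xd, color="0.2", s=12, zorder=2, edgecolors="none")
    ax.axhline(0.0, color="0.5", linewidth=0.8, zorder=1)
    ax.axvline(0.0, color="0.5", linewidth=0.8, zorder=1)
    ax.set_xlim(-lim_x, lim_x)
    ax.set_ylim(-lim_y, lim_y)
    ax.set_xlabel(r"true change $y^\Delta_t$")
    ax.set_ylabel(r"predicted change $x^\Delta_t$")
    n_conc = int((xd * yd > 0).sum())
    ax.set_title(f"concordant {n_conc} / {len(pairs)}")
    return _finish(fig, path), ax


def rolling_plot(curves: dict[str, pd.Series] | pd.Series, path=None, ax=None):
    """Rolling ATC ratio over time; accepts several labelled curves."""
    if isinstance(curves, pd.Series):
        curves = {curves.name or "rolling ATC": curves}
    fig, ax = _new_axes(ax)
    for label, series in curves.items():
        ax.plot(series.index, series.to_numpy(), label=label)
    ax.set_ylim(0.0, 1.0)
    ax.set_xlabel("time index t")
    ax.set_ylabel("rolling ATC ratio")
    if len(curves) > 1:
        ax.legend(frameon=False)
    return _finish(fig, path), ax


def exclusion_sweep_plot(
    tables: dict[str, pd.DataFrame] | pd.DataFrame, path=None, ax=None
):
    """ATC ratio against exclusion-area size (gaps where undefined)."""
    if isinstance(tables, pd.DataFrame):
        tables = {"ATC ratio": tables}
    fig, ax = _new_axes(ax)
    for label, table in tables.items():
        ax.plot(table["size"], table["value"], marker=".", label=label)
    ax.set_xlabel("exclusion area size")
    ax.set_ylabel("ATC ratio")
    if len(tables) > 1:
        ax.legend(frameon=False)
    return _finish(fig, path), ax


def conditional_plot(
    curves: dict[str, ConditionalATCCurve] | ConditionalATCCurve,
    reference=None,
    path=None,
    ax=None,
):
    """Conditional ATC curves, optionally with a dashed reference curve."""
    if isinstance(curves, ConditionalATCCurve):
        curves = {"conditional ATC": curves}
    fig, ax = _new_axes(ax)
    for label, curve in curves.items():
        ax.plot(curve.chi, curve.p, label=label)
    if reference is not None:
        chi = next(iter(curves.values())).chi
        ax.plot(chi, reference(chi), "k--", linewidth=1, label="theoretical")
    ax.set_ylim(0.0, 1.0)
    ax.set_xlabel(r"predicted change $\chi$")
    ax.set_ylabel(r"$P(\mathrm{correct\ direction} \mid X^\Delta = \chi)$")
    ax.legend(frameon=False)
    return _finish(fig, path), ax


def reliability_plot(
    tables: dict[str, pd.DataFrame] | pd.DataFrame, path=None, ax=None
):
    """Reliability diagram with the 45-degree reference line.

    Empty bins (count 0, NaN frequency) are skipped, not drawn at zero.
    """
    if isinstance(tables, pd.DataFrame):
        tables = {"model": tables}
    fig, ax = _new_axes(ax)
    ax.plot([0, 1], [0, 1], "k--", linewidth=1, zorder=1)
    for label, table in tables.items():
        filled = table[table["count"] > 0]
        ax.plot(filled["mean_p"], filled["obs_freq"], marker="o", label=label)
    ax.set_xlim(0.0, 1.0)
    ax.set_ylim(0.0, 1.0)
    ax.set_xlabel("predicted probability of increase")
    ax.set_ylabel("observed increase frequency")
    if len(tables) > 1:
        ax.legend(frameon=False)
    return _finish(fig, path), ax
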