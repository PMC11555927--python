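"""Conditional ATC curves via bivariate kernel density estimation.

The conditional ATC curve is P(XΔ·YΔ > 0 | XΔ = χ): how credible the
*direction* of a specific predicted change χ is.  For χ > 0 it equals
∫₀^∞ f(χ, y) dy / f_X(χ) and for χ < 0 the integral over (−∞, 0); at
χ = 0 it is undefined.

With a product-Gaussian kernel both pieces are available in closed
form: each kernel centred at (x_i, y_i) contributes a weight
φ((χ − x_i)/b_x) to the marginal and a tail mass Φ(±y_i/b_y) to the
half-plane integral, so the curve is a weight-normalised mixture of
normal CDF terms.  No quadrature and no associated tolerance knob.

Bandwidth selection is delegated to statsmodels' ``KDEMultivariate``:
``rule_of_thumb`` (normal reference, covariance-based), ``cv_ml``
(leave-one-out maximum-likelihood cross-validation; the default and the
recommended choice), and ``cv_ls`` (least-squares cross-validation,
available but known to be slow and prone to collapsing bandwidths, so
never a default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .changes import PairedChangeSeries

__all__ = [
    "SELECTORS",
    "KDEModel",
    "ConditionalATCCurve",
    "fit_kde",
    "joint_pdf",
    "conditional_curve",
    "theoretical_curve_bivnormal",
]

# Mapping from our selector names to statsmodels bandwidth arguments.
SELECTORS = {
    "rule_of_thumb": "normal_reference",
    "cv_ml": "cv_ml",
    "cv_ls": "cv_ls",
}


@dataclass(frozen=True)
class KDEModel:
    """Fitted product-Gaussian-kernel joint density of (xΔ, yΔ)."""

    x: np.ndarray
    y: np.ndarray
    bw_x: float
    bw_y: float
    selector: str

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class ConditionalATCCurve:
    """Estimated P(correct direction | XΔ = χ) on a sorted χ grid.

    Grid points where the marginal density is below the floor carry NaN.
    """

    chi: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if chi.shape != p.shape or chi.ndim != 1:
            raise ValueError("chi and p must be 1-d arrays of equal length")
        if np.any(np.diff(chi) <= 0):
            raise ValueError("chi grid must be strictly increasing")
        finite = p[np.isfinite(p)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "chi", chi)
        object.__setattr__(self, "p", np.clip(p, 0.0, 1.0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"chi": self.chi, "p": self.p})


def fit_kde(pairs: PairedChangeSeries, selector: str = "cv_ml") -> KDEModel:
    """Fit the bivariate KDE of (xΔ, yΔ) with per-axis bandwidths."""
    if selector not in SELECTORS:
        raise ValueError(f"selector must be one of {tuple(SELECTORS)}")
    x = np.asarray(pairs.x_delta, dtype=float)
    y = np.asarray(pairs.y_delta, dtype=float)
    if x.size < 10:
        raise ValueError("KDE requires at least 10 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError(
            "zero-variance component: jitter the data or use rule_of_thumb "
            "on the informative axis"
        )
    from statsmodels.nonparametric.kernel_density import KDEMultivariate

    kde = KDEMultivariate(data=[x, y], var_type="cc", bw=SELECTORS[selector])
    bw_x, bw_y = float(kde.bw[0]), float(kde.bw[1])
    if bw_x <= 0.0 or bw_y <= 0.0:
        raise ValueError(
            f"{selector} produced a nonpositive bandwidth ({bw_x}, {bw_y}); "
            "this is a known failure mode of cv_ls"
        )
    return KDEModel(x=x, y=y, bw_x=bw_x, bw_y=bw_y, selector=selector)


def joint_pdf(model: KDEModel, x_pts, y_pts) -> np.ndarray:
    """Joint density on the meshgrid of ``x_pts`` × ``y_pts``."""
    x_pts = np.asarray(x_pts, dtype=float)
    y_pts = np.asarray(y_pts, dtype=float)
    wx = norm.pdf((x_pts[:, None] - model.x[None, :]) / model.bw_x) / model.bw_x
    wy = norm.pdf((y_pts[:, None] - model.y[None, :]) / model.bw_y) / model.bw_y
    return wx @ wy.T / len(model)


def default_chi_grid(
    model: KDEModel,
    n_points: int = 201,
    quantile_range: tuple[float, float] = (0.01, 0.99),
    exclude_eps: float = 0.0,
) -> np.ndarray:
    """Evenly spaced χ between inner sample quantiles, skipping χ = 0.

    The curve is undefined at 0 and unstable in the density tails, hence
    the trimmed range.  With ``exclude_eps > 0`` (an x-band exclusion) a
    neighbourhood of 0 is removed as well.
    """
    lo, hi = np.quantile(model.x, quantile_range)
    grid = np.linspace(lo, hi, n_points)
    keep = grid != 0.0
    if exclude_eps > 0.0:
        keep &= np.abs(grid) > exclude_eps
    return grid[keep]


def conditional_curve(
    model: KDEModel,
    chi_grid=None,
    n_points: int = 201,
    exclude_eps: float = 0.0,
    density_floor: float = 1e-12,
) -> ConditionalATCCurve:
    """Evaluate the conditional ATC curve on a χ grid.

    The half-plane integrals are closed-form Gaussian-mixture tail sums;
    grid points where the estimated marginal f_X(χ) falls below
    ``density_floor`` are emitted as NaN rather than divided through.
    """
    if chi_grid is None:
        chi = default_chi_grid(model, n_points, exclude_eps=exclude_eps)
    else:
        chi = np.asarray(chi_grid, dtype=float)
        if np.any(chi == 0.0):
            raise ValueError("the conditional curve is undefined at chi = 0")
    # Unnormalized kernel weights; normalization cancels in the ratio.
    w = norm.pdf((chi[:, None] - model.x[None, :]) / model.bw_x)
    w_sum = w.sum(axis=1)
    f_x = w_sum / (len(model) * model.bw_x)
    # P(kernel i contributes mass above / below zero in y).
    tail_pos = norm.cdf(model.y / model.bw_y)
    mass = np.where(chi[:, None] > 0, tail_pos[None, :], 1.0 - tail_pos[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (w * mass).sum(axis=1) / w_sum
    p = np.where(f_x < density_floor, np.nan, p)
    return ConditionalATCCurve(chi=chi, p=p)


def theoretical_curve_bivnormal(chi) -> np.ndarray | float:
    """Exact concordance curve of the Σ=[[4,3],[3,4]] bivariate normal.

    Conditional on XΔ = χ, YΔ is normal with mean 3χ/4 and variance
    4 − 9/4 = 7/4, so the probability of matching sign is
    Φ(3|χ|/(2√7)) — symmetric in χ because concordance flips with the
    sign of the conditioning value.
    """
    chi = np.asarray(chi, dtype=float)
    out = norm.cdf(3.0 * np.abs(chi) / (2.0 * np.sqrt(7.0)))
    return float(out) if out.ndim == 0 else out
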