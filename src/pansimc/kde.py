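"""Bivariate Gaussian kernel density estimation of a score-pair joint PDF.

The target density pi(x) over a 2-D score pair is approximated by a product
Gaussian kernel smoother:

    J(x) = (1 / (n h1 h2)) * sum_i phi((x1 - p_i1)/h1) * phi((x2 - p_i2)/h2)

with phi the standard normal density and per-dimension bandwidths set by the
normal-reference rule for two dimensions, h_d = sigma_d * n^(-1/6) (sample
standard deviation, ddof=1). Integer scores are used as-is; the smooth
density extends beyond the valid score rectangle, which is absorbed at
binning time by extending the outer bins to +/- infinity (see
:mod:`pansimc.prob_tables`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["KdeModel", "fit_kde", "density", "grid_mass", "cell_mass"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class KdeModel:
    """A fitted product-Gaussian KDE over an (n, 2) point cloud."""

    points: np.ndarray
    bandwidths: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if pts.shape[0] < 2:
            raise ValueError("need at least 2 points")
        h1, h2 = self.bandwidths
        if not (h1 > 0 and h2 > 0):
            raise ValueError("bandwidths must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def fit_kde(points: np.ndarray, bandwidths: tuple[float, float] | None = None) -> KdeModel:
    """Fit the KDE; bandwidths default to ``sigma_d * n**(-1/6)`` per axis.

    Raises ``ValueError`` for a zero-variance coordinate — jitter the scores
    or widen the cohort before fitting.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to fit a KDE")
    if bandwidths is None:
        sd = pts.std(axis=0, ddof=1)
        if np.any(sd == 0):
            dim = int(np.argmax(sd == 0))
            raise ValueError(
                f"coordinate {dim} has zero sample variance; jitter the "
                "scores or widen the cohort before fitting a KDE"
            )
        bandwidths = tuple(sd * n ** (-1.0 / 6.0))
    return KdeModel(points=pts, bandwidths=(float(bandwidths[0]), float(bandwidths[1])))


def density(model: KdeModel, x: np.ndarray) -> float | np.ndarray:
    """Evaluate J(x) at one 2-vector (returns a float) or an (m, 2) array.

    Computed in log space per point and summed with exp, so far-tail queries
    underflow gracefully to 0 rather than producing NaN.
    """
    q = np.atleast_2d(np.asarray(x, dtype=float))
    h1, h2 = model.bandwidths
    # (m, n) standardized residuals per axis
    z1 = (q[:, None, 0] - model.points[None, :, 0]) / h1
    z2 = (q[:, None, 1] - model.points[None, :, 1]) / h2
    logk = -0.5 * (z1 * z1 + z2 * z2) - _LOG_2PI
    vals = np.exp(logk).sum(axis=1) / (model.n * h1 * h2)
    if np.asarray(x).ndim == 1:
        return float(vals[0])
    return vals


def grid_mass(
    model: KdeModel,
    xlim: tuple[float, float] | None = None,
    ylim: tuple[float, float] | None = None,
    nx: int = 200,
    ny: int = 200,
) -> float:
    """Midpoint Riemann sum of the density over a rectangular grid.

    Defaults to the point cloud's bounding box padded by 6 bandwidths, for
    which the sum approaches 1 as resolution grows (normalization check).
    Warns if the requested grid does not cover the padded support.
    """
    import warnings

    h1, h2 = model.bandwidths
    lo = model.points.min(axis=0)
    hi = model.points.max(axis=0)
    support_x = (lo[0] - 6 * h1, hi[0] + 6 * h1)
    support_y = (lo[1] - 6 * h2, hi[1] + 6 * h2)
    if xlim is None:
        xlim = support_x
    if ylim is None:
        ylim = support_y
    if xlim[0] > support_x[0] or xlim[1] < support_x[1] or ylim[0] > support_y[0] or ylim[1] < support_y[1]:
        warnings.warn("grid does not cover the points +/- 6 bandwidths", stacklevel=2)
    if nx < 1 or ny < 1 or xlim[0] >= xlim[1] or ylim[0] >= ylim[1]:
        return 0.0
    dx = (xlim[1] - xlim[0]) / nx
    dy = (ylim[1] - ylim[0]) / ny
    xs = xlim[0] + dx * (np.arange(nx) + 0.5)
    ys = ylim[0] + dy * (np.arange(ny) + 0.5)
    total = 0.0
    # evaluate one grid row at a time to keep memory at O(ny * n)
    for xv in xs:
        row = np.column_stack([np.full(ny, xv), ys])
        total += density(model, row).sum()
    return float(total * dx * dy)


def cell_mass(
    model: KdeModel,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> float:
    """Exact KDE mass over an axis-aligned rectangle.

    For a product-Gaussian kernel the integral factorizes into normal CDF
    differences per point; ranges may be infinite. Used as the quadrature
    reference for Monte Carlo probability tables.
    """
    h1, h2 = model.bandwidths
    p = model.points
    mx = norm.cdf((x_range[1] - p[:, 0]) / h1) - norm.cdf((x_range[0] - p[:, 0]) / h1)
    my = norm.cdf((y_range[1] - p[:, 1]) / h2) - norm.cdf((y_range[0] - p[:, 1]) / h2)
    return float(np.mean(mx * my))
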