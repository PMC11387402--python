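"""Chain-length and saturation structure of differential results.

VLCFA incorporation shows up as fold changes that grow with the total
acyl-carbon number within a lipid class. Per class, the log2 fold changes
are plotted against total chain length and smoothed with a LOESS curve
(tricube-weighted local polynomial regression); the (length x
unsaturation) matrix of log2 fold changes gives the saturation heatmap.
Only the length axis is smoothed; heatmap cells carry the raw per-lipid
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .chem import parse_lipid_name
from .stats import correlate

logger = logging.getLogger(__name__)

__all__ = [
    "loess_fit",
    "LoessRegressor",
    "ChainTrend",
    "chain_trend",
    "saturation_heatmap",
]


def loess_fit(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    grid=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial regression (LOESS).

    At each grid point the nearest ``ceil(span * n)`` observations get
    tricube weights ``(1 - (d/h)^3)^3`` with ``h`` the bandwidth (distance
    to the farthest included point) and a degree-``degree`` polynomial is
    fit by weighted least squares; the fitted value is its evaluation at
    the grid point. With ``span=1``, ``degree=1`` and exactly collinear
    data this reproduces the line.

    Returns (grid, fitted values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    n_distinct = len(np.unique(x))
    if n_distinct < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} distinct x values, "
            f"got {n_distinct}"
        )
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 1)
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        dist = np.abs(x - x0)
        order = np.argsort(dist, kind="stable")
        h = dist[order[min(k, n) - 1]]
        if h == 0:
            # duplicate-heavy neighborhood: average the coincident points
            fitted[i] = y[dist == 0].mean()
            continue
        w = np.clip(1 - (dist / h) ** 3, 0, None) ** 3
        use = w > 0
        if np.count_nonzero(use) <= degree:  # widen until solvable
            use = order[: degree + 1]
            w = np.ones(n)
        xc = x[use] - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[use] * sw, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted


class LoessRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper around :func:`loess_fit`."""

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, X, y):
        self.x_ = np.asarray(X, dtype=float).ravel()
        self.y_ = np.asarray(y, dtype=float).ravel()
        loess_fit(self.x_, self.y_, self.span, self.degree, grid=self.x_[:1])
        return self

    def predict(self, X):
        grid = np.asarray(X, dtype=float).ravel()
        _, fitted = loess_fit(self.x_, self.y_, self.span, self.degree, grid=grid)
        return fitted


@dataclass
class ChainTrend:
    """LOESS trend of log2 fold change vs total chain length for one class."""

    class_code: str
    points: pd.DataFrame  # columns: total_carbons, log2_fold_change, double_bonds
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))
    span: float = 0.75
    degree: int = 2
    monotone_spearman: float = float("nan")  # Spearman(fitted curve, grid)
    points_spearman: float = float("nan")  # Spearman(raw log2FC, carbons)

    @property
    def empty(self) -> bool:
        return len(self.grid) == 0


def _class_points(results: pd.DataFrame, class_code: str) -> pd.DataFrame:
    rows = []
    for lipid in results.index:
        try:
            parsed = parse_lipid_name(str(lipid))
        except ValueError:
            continue
        if parsed.class_code != class_code:
            continue
        rows.append(
            {
                "lipid": str(lipid),
                "total_carbons": parsed.total_carbons,
                "double_bonds": parsed.total_double_bonds,
                "log2_fold_change": float(results.loc[lipid, "log2_fold_change"]),
            }
        )
    return pd.DataFrame(rows)


def chain_trend(
    results: pd.DataFrame,
    class_code: str,
    span: float = 0.75,
    degree: int = 2,
) -> ChainTrend:
    """Per-class LOESS trend of log2 fold change against total carbons.

    Two monotone-increase statistics are reported: the Spearman
    correlation of the fitted curve with the carbon grid (descriptive —
    smoothing inflates it under a null), and the Spearman correlation of
    the raw per-lipid log2 fold changes with total carbons, which is the
    calibrated statistic to use for null behavior. Fewer than 3 lipids in
    the class gives an empty trend with a warning.
    """
    points = _class_points(results, class_code)
    if len(points) < 3:
        logger.warning(
            "class %s: %d lipid(s) in results; no trend fit", class_code, len(points)
        )
        return ChainTrend(class_code, points, span=span, degree=degree)
    finite = points[np.isfinite(points["log2_fold_change"])]
    grid, fitted = loess_fit(
        finite["total_carbons"].to_numpy(float),
        finite["log2_fold_change"].to_numpy(float),
        span=span,
        degree=degree,
    )
    rho_fit = rho_pts = float("nan")
    if len(grid) >= 3 and np.ptp(fitted) > 0:
        rho_fit, _ = correlate(fitted, grid, method="spearman")
    if len(finite) >= 3 and np.ptp(finite["log2_fold_change"]) > 0:
        rho_pts, _ = correlate(
            finite["log2_fold_change"], finite["total_carbons"], method="spearman"
        )
    return ChainTrend(
        class_code, points, grid, fitted, span, degree, rho_fit, rho_pts
    )


def saturation_heatmap(results: pd.DataFrame, class_code: str) -> pd.DataFrame:
    """(total carbons) x (double bonds) matrix of log2 fold changes.

    One cell per (n, d) present in the results; duplicate sum compositions
    within the class violate uniqueness and raise. Cells carry the exact
    per-lipid log2 fold change, unsmoothed.
    """
    points = _class_points(results, class_code)
    if points.empty:
        return pd.DataFrame()
    dup = points.duplicated(subset=["total_carbons", "double_bonds"])
    if dup.any():
        pairs = points.loc[dup, ["total_carbons", "double_bonds"]].to_records(
            index=False
        )
        raise ValueError(
            f"duplicate sum compositions in class {class_code}: {list(pairs)}"
        )
    return points.pivot(
        index="total_carbons", columns="double_bonds", values="log2_fold_change"
    )
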