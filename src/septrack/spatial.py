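"""Standardized-cell spatial statistics for single-molecule localizations.

Localizations from cells of different sizes are projected into a common
3 x 1 µm reference frame ("standardized cell"): the along-axis coordinate
``u`` runs from -1.5 µm (pole 1) to +1.5 µm (pole 2) and the across-axis
coordinate ``v`` from -0.5 to +0.5 µm, scaled by the local cell half-width.
Pole 1 is, by convention, the pole with the lower localization count, so
pole-resolved statistics are orientation-free.

From the standardized points the module computes population heatmaps and
difference heatmaps (0.1 µm pixels), per-cell demographs (rows sorted by
cell length), midcell/polar proportions and the polar ratio (each region
spanning 20% of the cell length), the most-populated axial position, and
LOESS trends of any statistic against cell length (the cell-cycle proxy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from sklearn.base import BaseEstimator

from .tracking import CellOutline

__all__ = [
    "StandardizedPoints",
    "LocalizationStats",
    "normalize_to_standard_cell",
    "build_heatmap",
    "diff_heatmap",
    "build_demograph",
    "compute_localization_stats",
    "LoessRegression",
    "loess_trend",
]

#: standardized cell half-length and half-width, µm
_HALF_L = 1.5
_HALF_W = 0.5


@dataclass
class LocalizationStats:
    """Per-cell localization summary (regions span 20% of the cell length)."""

    cell_id: str
    length: float  # µm
    septum: bool
    midcell_prop: float
    polar_prop: float
    polar_ratio: float  # lesser pole / greater pole, in [0, 1]
    max_location: float  # µm along the axis, 0 = midcell
    n_points: int


StandardizedPoints = pd.DataFrame  # columns u, v, s_um, cell_id


def _halfwidth_profile(outline: CellOutline, n_stations: int = 101):
    """Sample the perpendicular half-widths of the outline along the
    pole-to-pole axis (positive and negative sides separately)."""
    p1, p2 = outline.poles
    axis = p2 - p1
    L = np.linalg.norm(axis)
    u_hat = axis / L
    n_hat = np.array([-u_hat[1], u_hat[0]])
    poly = outline.polygon
    reach = max(L, 10.0)
    ts = np.linspace(0.0, L, n_stations)
    h_pos = np.full(n_stations, 1e-9)
    h_neg = np.full(n_stations, 1e-9)
    for i, t in enumerate(ts):
        base = p1 + t * u_hat
        chord = LineString([base - reach * n_hat, base + reach * n_hat])
        seg = chord.intersection(poly)
        if seg.is_empty:
            continue
        coords = []
        if seg.geom_type == "LineString":
            coords = list(seg.coords)
        elif seg.geom_type == "MultiLineString":
            for part in seg.geoms:
                coords.extend(part.coords)
        elif seg.geom_type == "Point":
            coords = [(seg.x, seg.y)]
        if not coords:
            continue
        offs = [float(np.dot(np.asarray(c) - base, n_hat)) for c in coords]
        h_pos[i] = max(max(offs, default=0.0), 1e-9)
        h_neg[i] = max(-min(offs, default=0.0), 1e-9)
    return ts, h_pos, h_neg


def normalize_to_standard_cell(
    locs: pd.DataFrame, outline: CellOutline
) -> StandardizedPoints:
    """Project localizations of one cell into the 3 x 1 µm standardized frame.

    The along-axis coordinate is the signed projection onto the pole-to-pole
    axis rescaled so the poles map to u = ±1.5; the across-axis offset is
    rescaled by the local half-width so the membrane maps to v = ±0.5.  The
    orientation is then fixed so that the pole with fewer localizations lies
    at negative u.  Also returns ``s_um``, the along-axis coordinate in real
    µm (0 at midcell, same orientation as u).
    """
    p1, p2 = outline.poles.astype(float)
    axis = p2 - p1
    L = float(np.linalg.norm(axis))
    if L < 1e-9:
        raise ValueError(f"cell {outline.cell_id}: poles coincide")
    u_hat = axis / L
    n_hat = np.array([-u_hat[1], u_hat[0]])

    xy = locs[["x_um", "y_um"]].to_numpy(dtype=float)
    rel = xy - p1
    t = rel @ u_hat
    d = rel @ n_hat
    frac = np.clip(t / L, 0.0, 1.0)
    u = (frac - 0.5) * 2.0 * _HALF_L
    s_um = (frac - 0.5) * L

    ts, h_pos, h_neg = _halfwidth_profile(outline)
    hp = np.interp(frac * L, ts, h_pos)
    hn = np.interp(frac * L, ts, h_neg)
    v = np.where(d >= 0, d / hp, d / hn) * _HALF_W
    v = np.clip(v, -_HALF_W, _HALF_W)

    # orientation: the pole with fewer localizations maps to negative u
    if np.sum(u < 0) > np.sum(u > 0):
        u = -u
        s_um = -s_um
        v = -v
    out = pd.DataFrame({"u": u, "v": v, "s_um": s_um})
    out["cell_id"] = outline.cell_id
    return out


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

def build_heatmap(points: pd.DataFrame, pixel: float = 0.1) -> np.ndarray:
    """Proportion grid of standardized points (default 30 x 10 at 0.1 µm).

    Axis 0 is the along-axis coordinate u, axis 1 the across-axis v; entries
    sum to 1.
    """
    if len(points) == 0:
        raise ValueError("no points: proportions undefined")
    nu = int(round(2 * _HALF_L / pixel))
    nv = int(round(2 * _HALF_W / pixel))
    counts, _, _ = np.histogram2d(
        points["u"], points["v"], bins=[nu, nv],
        range=[[-_HALF_L, _HALF_L], [-_HALF_W, _HALF_W]],
    )
    return counts / counts.sum()


def diff_heatmap(grid_a: np.ndarray, grid_b: np.ndarray) -> np.ndarray:
    """Elementwise difference of two proportion grids (a - b)."""
    grid_a = np.asarray(grid_a)
    grid_b = np.asarray(grid_b)
    if grid_a.shape != grid_b.shape:
        raise ValueError("grids must have the same shape")
    return grid_a - grid_b


# ---------------------------------------------------------------------------
# demograph
# ---------------------------------------------------------------------------

def build_demograph(
    points: pd.DataFrame,
    lengths: dict[str, float] | pd.Series,
    binwidth: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """Stack per-cell axial localization densities sorted by cell length.

    ``points`` must carry ``cell_id`` and ``s_um`` (axial position in µm,
    0 = midcell, *actual* cell scale).  Each row is binned at ``binwidth``
    over that cell's own length, centre-aligned in a common
    ``[-L_max/2, L_max/2]`` frame, and normalized to a maximum of 1.

    Returns ``(matrix, cell_ids)`` with rows in ascending-length order.
    """
    lengths = pd.Series(lengths)
    if len(lengths) == 0:
        raise ValueError("need at least one cell")
    order = lengths.sort_values(kind="mergesort").index.tolist()
    l_max = float(lengths.max())
    n_bins = max(1, int(np.ceil(l_max / binwidth)))
    edges = np.linspace(-l_max / 2, l_max / 2, n_bins + 1)
    mat = np.zeros((len(order), n_bins))
    grouped = dict(tuple(points.groupby("cell_id")))
    for row, cid in enumerate(order):
        grp = grouped.get(cid)
        if grp is None or len(grp) == 0:
            continue
        L = lengths[cid]
        s = grp["s_um"].to_numpy()
        s = s[(s >= -L / 2) & (s <= L / 2)]
        hist, _ = np.histogram(s, bins=edges)
        if hist.max() > 0:
            mat[row] = hist / hist.max()
    return mat, order


# ---------------------------------------------------------------------------
# per-cell statistics
# ---------------------------------------------------------------------------

def compute_localization_stats(
    points: pd.DataFrame,
    outline: CellOutline,
    region_frac: float = 0.2,
    binwidth: float = 0.1,
) -> LocalizationStats:
    """Midcell/polar proportions, polar ratio, and max axial location.

    The midcell region is the central ``region_frac`` of the cell length and
    each polar region the terminal ``region_frac`` (all in the standardized
    frame, boundaries inclusive).  ``polar_prop`` sums both poles.  The polar
    ratio is (count at lesser pole) / (count at greater pole), 0 when only
    the greater pole has counts, NaN when both are empty.  ``max_location``
    is the centre of the most-populated axial bin (ties broken toward
    midcell), in real µm.
    """
    if len(points) == 0:
        raise ValueError("no points in cell")
    u = points["u"].to_numpy()
    n = len(u)
    mid_half = region_frac * 2 * _HALF_L / 2  # e.g. 0.3 µm for 20%
    pole_cut = _HALF_L - region_frac * 2 * _HALF_L / 2 * 2  # 1.5 - 0.6 = 0.9
    mid = np.sum(np.abs(u) <= mid_half)
    pole_neg = np.sum(u <= -pole_cut)
    pole_pos = np.sum(u >= pole_cut)
    lesser, greater = sorted([pole_neg, pole_pos])
    if greater == 0:
        ratio = np.nan
    elif lesser == 0:
        ratio = 0.0
    else:
        ratio = lesser / greater

    s = points["s_um"].to_numpy()
    L = outline.length
    n_bins = max(1, int(np.ceil(L / binwidth)))
    edges = np.linspace(-L / 2, L / 2, n_bins + 1)
    hist, _ = np.histogram(s, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = hist.max()
    candidates = np.flatnonzero(hist == best)
    max_loc = centers[candidates[np.argmin(np.abs(centers[candidates]))]]

    return LocalizationStats(
        cell_id=outline.cell_id,
        length=float(L),
        septum=bool(outline.septum),
        midcell_prop=float(mid / n),
        polar_prop=float((pole_neg + pole_pos) / n),
        polar_ratio=float(ratio),
        max_location=float(max_loc),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

class LoessRegression(BaseEstimator):
    """Local linear regression with tricube weights (LOESS, degree 1).

    At each evaluation point the ``span`` fraction of nearest neighbours is
    weighted by the tricube kernel and a weighted straight line is fitted;
    the pointwise standard error comes from the linear-smoother form
    ``se(x0) = sigma * ||l(x0)||`` with a global residual variance estimate.
    """

    def __init__(self, span: float = 0.75):
        self.span = span

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(x) != len(y):
            raise ValueError("x and y must have the same length")
        if len(x) < 10:
            raise ValueError("LOESS requires at least 10 points")
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        order = np.argsort(x, kind="mergesort")
        self.x_ = x[order]
        self.y_ = y[order]
        # global residual scale from in-sample fits
        fitted = np.array([self._smooth(xi)[0] for xi in self.x_])
        resid = self.y_ - fitted
        dof = max(len(x) - 2, 1)
        self.sigma_ = float(np.sqrt(np.sum(resid**2) / dof))
        return self

    def _smooth(self, x0: float) -> tuple[float, float]:
        """Fitted value and ||l(x0)|| of the equivalent-kernel weights."""
        x, y = self.x_, self.y_
        n = len(x)
        q = max(2, int(np.ceil(self.span * n)))
        d = np.abs(x - x0)
        h = np.partition(d, min(q, n) - 1)[min(q, n) - 1]
        if h <= 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        active = w > 0
        xa, ya, wa = x[active], y[active], w[active]
        X = np.column_stack([np.ones(len(xa)), xa - x0])
        XtW = X.T * wa
        A = XtW @ X
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        l_active = (Ainv @ XtW)[0]  # weights giving the fit at x0
        return float(l_active @ ya), float(np.sqrt(np.sum(l_active**2)))

    def predict(self, X, return_se: bool = False):
        x0s = np.asarray(X, dtype=float).ravel()
        yhat = np.empty(len(x0s))
        lnorm = np.empty(len(x0s))
        for i, x0 in enumerate(x0s):
            yhat[i], lnorm[i] = self._smooth(x0)
        if return_se:
            return yhat, self.sigma_ * lnorm
        return yhat


def loess_trend(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOESS trend of a statistic against cell length.

    Returns ``(grid, fitted, se)``; the default grid spans the observed x
    range.
    """
    est = LoessRegression(span=span).fit(x, y)
    if grid is None:
        grid = np.linspace(est.x_.min(), est.x_.max(), n_grid)
    fitted, se = est.predict(grid, return_se=True)
    return np.asarray(grid), fitted, se
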