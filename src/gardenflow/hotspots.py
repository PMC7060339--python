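"""Hotspots and coldspots of garden clustering (Getis-Ord Gi*).

Garden nodes are counted on a square fishnet (default 500 m, a walkable
distance that also bounds urban pollinator movement), and each cell's
neighbourhood count is compared with the citywide mean via the Gi*
statistic with binary fixed-distance-band weights (self included):

    Gi* = (sum_j w_ij x_j - Xbar sum_j w_ij)
          / ( S * sqrt[(n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1)] )

with Xbar the mean count, S the population SD.  z > +1 marks a hotspot
(clustered gardens), z < -1 a coldspot (isolation), in SD units.  Inverse
distance weighting interpolates the z-scores to a continuous surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError
from .grid import GridTransform, RasterGrid, rectangle


@dataclass
class HotspotGrid:
    """A fishnet of square cells with garden counts and Gi* results.

    ``cells`` has one row per fishnet cell (row-major from the north-west
    corner): row, col, cx, cy (centroid), count, and — after ``gi_star`` /
    ``classify`` — z, p, hotspot_class.
    """

    cells: pd.DataFrame
    cell_m: float
    nrows: int
    ncols: int
    extent: tuple[float, float, float, float]

    def polygons(self):
        half = self.cell_m / 2.0
        return [
            rectangle(r.cx - half, r.cy - half, r.cx + half, r.cy + half)
            for r in self.cells.itertuples()
        ]


def fishnet_counts(
    nodes: pd.DataFrame, extent: tuple[float, float, float, float], cell_m: float = 500.0
) -> HotspotGrid:
    """Count garden nodes per fishnet cell.

    A node exactly on a shared cell edge goes to the cell with the smaller
    row-major index (row 0 at the northern edge), a deterministic tie-break.
    """
    if cell_m <= 0:
        raise ConfigurationError("fishnet cell size must be > 0")
    if len(nodes) == 0:
        raise ConfigurationError("empty node set")
    xmin, ymin, xmax, ymax = extent
    ncols = int(np.ceil((xmax - xmin) / cell_m))
    nrows = int(np.ceil((ymax - ymin) / cell_m))

    x = nodes["x"].to_numpy(dtype=float)
    y = nodes["y"].to_numpy(dtype=float)
    col = np.floor((x - xmin) / cell_m).astype(int)
    row_from_top = np.floor((ymax - y) / cell_m).astype(int)
    # edge ties: a point exactly on a vertical edge would floor into the
    # higher column — pull it back to the smaller row-major index; same for
    # horizontal edges (which floor into the *smaller* row seen from top,
    # already the smaller index, except points exactly on the southern rim).
    on_v_edge = np.isclose((x - xmin) % cell_m, 0.0) & (col > 0)
    col = np.where(on_v_edge, col - 1, col)
    col = np.clip(col, 0, ncols - 1)
    row_from_top = np.clip(row_from_top, 0, nrows - 1)

    counts = np.zeros(nrows * ncols, dtype=int)
    np.add.at(counts, row_from_top * ncols + col, 1)

    rows, cols = np.divmod(np.arange(nrows * ncols), ncols)
    cx = xmin + (cols + 0.5) * cell_m
    cy = ymax - (rows + 0.5) * cell_m
    cells = pd.DataFrame(
        {"row": rows, "col": cols, "cx": cx, "cy": cy, "count": counts}
    )
    return HotspotGrid(cells, cell_m, nrows, ncols, extent)


def gi_star(grid: HotspotGrid, band_m: float = 500.0) -> HotspotGrid:
    """Gi* z-score and two-sided normal p-value per fishnet cell, with
    binary weights w_ij = 1 iff centroid distance <= band (self included)."""
    if band_m <= 0:
        raise ConfigurationError("distance band must be > 0")
    x = grid.cells["count"].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise ConfigurationError("Gi* needs at least 2 cells")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise DegenerateInputError("constant counts: Gi* variance is zero")

    cx = grid.cells["cx"].to_numpy()
    cy = grid.cells["cy"].to_numpy()
    # pairwise band membership; fishnets are modest (<= tens of thousands)
    d2 = (cx[:, None] - cx[None, :]) ** 2 + (cy[:, None] - cy[None, :]) ** 2
    w = d2 <= band_m**2 * (1 + 1e-12)
    wsum = w.sum(axis=1).astype(float)
    wx = w @ x
    denom = s * np.sqrt((n * wsum - wsum**2) / (n - 1))
    # a band covering the whole study area makes Gi* 0/0; the neighbourhood
    # sum then equals its expectation exactly, so z = 0
    whole = denom == 0
    z = np.zeros(n)
    z[~whole] = (wx[~whole] - xbar * wsum[~whole]) / denom[~whole]
    grid.cells["z"] = z
    grid.cells["p"] = 2 * stats.norm.sf(np.abs(z))
    return grid


def classify(grid: HotspotGrid, threshold: float = 1.0, use_median: bool = False) -> HotspotGrid:
    """Label cells hot (z above +threshold), cold (below -threshold), else
    neutral.  The z-score is already in SD units, so the default threshold
    of 1 marks the >1 SD / <-1 SD classes.  ``use_median`` centres the
    threshold on the median z instead of 0 (an alternative reading of
    'one SD from the median')."""
    if "z" not in grid.cells:
        raise ConfigurationError("run gi_star before classify")
    z = grid.cells["z"].to_numpy()
    centre = float(np.median(z)) if use_median else 0.0
    cls = np.where(
        z > centre + threshold, "hot", np.where(z < centre - threshold, "cold", "neutral")
    )
    grid.cells["hotspot_class"] = cls
    return grid


def idw_surface(
    grid: HotspotGrid,
    out_transform: GridTransform,
    shape: tuple[int, int],
    power: float = 2.0,
) -> RasterGrid:
    """Inverse-distance-weighted interpolation of the Gi* z-scores onto a
    raster; an output point coinciding with a fishnet centroid returns that
    cell's z exactly."""
    if power <= 0:
        raise ConfigurationError("IDW power must be > 0")
    if "z" not in grid.cells:
        raise ConfigurationError("run gi_star before idw_surface")
    z = grid.cells["z"].to_numpy(dtype=float)
    cx = grid.cells["cx"].to_numpy()
    cy = grid.cells["cy"].to_numpy()

    out = RasterGrid(np.zeros(shape), out_transform)
    xs, ys = out.cell_centers()
    qx, qy = xs.ravel(), ys.ravel()
    vals = np.empty(qx.size)
    # chunked to bound the (query x centroid) distance matrix
    chunk = max(1, 2_000_000 // max(1, z.size))
    for lo in range(0, qx.size, chunk):
        hi = min(lo + chunk, qx.size)
        d = np.sqrt(
            (qx[lo:hi, None] - cx[None, :]) ** 2 + (qy[lo:hi, None] - cy[None, :]) ** 2
        )
        exact_q, exact_c = np.nonzero(d == 0)
        with np.errstate(divide="ignore"):
            wgt = d ** (-power)
        wgt[exact_q, :] = 0.0
        wgt[exact_q, exact_c] = 1.0
        vals[lo:hi] = (wgt @ z) / wgt.sum(axis=1)
    return RasterGrid(vals.reshape(shape), out_transform)
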