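"""Raster grids, georeferencing, and plain-text geospatial I/O.

Rasters are square-celled, north-up, row-major grids (row 0 is the northern
edge) referenced by the lower-left corner of the extent, the convention of
the ESRI ASCII Grid format used for on-disk storage.  Vector layers (points,
polygons) are shapely geometries serialized to GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .errors import SchemaError

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Georeferencing of a north-up raster: lower-left corner + cell size."""

    xll: float
    yll: float
    cell: float

    def cell_center(self, row, col, nrows: int):
        """Map-unit coordinates of cell centers (row 0 = top)."""
        x = self.xll + (np.asarray(col) + 0.5) * self.cell
        y = self.yll + (nrows - np.asarray(row) - 0.5) * self.cell
        return x, y

    def locate(self, x, y, nrows: int, ncols: int):
        """Cell indices containing map points; -1 where outside the grid."""
        col = np.floor((np.asarray(x, dtype=float) - self.xll) / self.cell).astype(int)
        row = nrows - 1 - np.floor(
            (np.asarray(y, dtype=float) - self.yll) / self.cell
        ).astype(int)
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        return np.where(ok, row, -1), np.where(ok, col, -1)


class RasterGrid:
    """A 2-D value grid with a validity mask and georeferencing.

    Parameters
    ----------
    values : array of shape (nrows, ncols)
        Cell values; entries where ``mask`` is False are ignored.
    transform : GridTransform
        Location of the lower-left corner and the cell size in map units.
    mask : boolean array, optional
        True where the cell carries data.  Defaults to all-valid.
    """

    def __init__(self, values, transform: GridTransform, mask=None):
        self.values = np.asarray(values)
        if self.values.ndim != 2:
            raise SchemaError("raster values must be 2-D")
        self.transform = transform
        if mask is None:
            mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise SchemaError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        t = self.transform
        return (
            t.xll,
            t.yll,
            t.xll + self.ncols * t.cell,
            t.yll + self.nrows * t.cell,
        )

    def cell_centers(self):
        """Coordinate arrays (x, y), each of shape (nrows, ncols)."""
        rows, cols = np.meshgrid(
            np.arange(self.nrows), np.arange(self.ncols), indexing="ij"
        )
        return self.transform.cell_center(rows, cols, self.nrows)

    def sample(self, x, y):
        """Values at map points; (values, valid_flag). Outside/nodata → invalid."""
        row, col = self.transform.locate(x, y, self.nrows, self.ncols)
        inside = row >= 0
        r = np.where(inside, row, 0)
        c = np.where(inside, col, 0)
        valid = inside & self.mask[r, c]
        vals = np.where(valid, self.values[r, c], np.nan)
        return vals, valid

    def copy_with(self, values=None, mask=None) -> "RasterGrid":
        return RasterGrid(
            self.values.copy() if values is None else values,
            self.transform,
            self.mask.copy() if mask is None else mask,
        )


def write_ascii_grid(raster: RasterGrid, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a RasterGrid as an ESRI ASCII Grid (.asc) text raster."""
    t = raster.transform
    vals = np.where(raster.mask, raster.values.astype(float), NODATA)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {t.xll:.10g}\n"
        f"yllcorner {t.yll:.10g}\n"
        f"cellsize {t.cell:.10g}\n"
        f"NODATA_value {NODATA:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII Grid text raster into a RasterGrid."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", NODATA)
    if "xllcorner" not in header:
        raise SchemaError(f"{path}: not an ESRI ASCII grid (missing xllcorner)")
    transform = GridTransform(header["xllcorner"], header["yllcorner"], header["cellsize"])
    mask = vals != nodata
    return RasterGrid(vals, transform, mask)


def write_geojson(
    geometries: Iterable, path: str | Path, properties: Sequence[dict] | None = None
) -> None:
    """Write shapely geometries (+ per-feature properties) as GeoJSON."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path):
    """Read GeoJSON into (list of shapely geometries, list of property dicts)."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties") or {} for f in doc["features"]]
    return geoms, props


def rectangle(xmin: float, ymin: float, xmax: float, ymax: float):
    return shapely.box(xmin, ymin, xmax, ymax)
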