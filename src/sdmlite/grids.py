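"""Aligned stacks of single-band geographic rasters.

A :class:`ClimateStack` holds one or more bioclimatic layers (Bio1..Bio19 in the
WorldClim naming) on a shared regular lon/lat grid, together with a shared
validity mask: a cell is invalid (``nodata``, typically ocean) as soon as any
layer is nodata there.  All point-to-cell arithmetic in the package goes
through :meth:`ClimateStack.point_to_cell`, which is the single authority for
the grid convention:

* row 0 is the northernmost row;
* cell ``(0, 0)`` covers the half-open box
  ``[x0, x0 + res) x (y0 - res, y0]`` measured from the north-west corner
  ``(x0, y0)``, so every boundary point belongs to exactly one cell.

Two on-disk formats are supported: the ESRI ASCII grid dialect (plain text,
human-diffable, used by all shipped fixtures) and single-band GeoTIFF written
through :mod:`tifffile` with the standard GeoTIFF georeferencing tags.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateStack",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_raster_stack",
    "write_raster",
    "extract_values",
    "crop_stack",
]

DEFAULT_NODATA = -9999.0

#: column names reserved for metadata in a sample matrix; every other column
#: is a climate variable.
SAMPLE_META_COLUMNS = ("lon", "lat", "label")


class AlignmentError(ValueError):
    """Raised when rasters meant to form a stack do not share one grid."""


@dataclass
class ClimateStack:
    """An aligned multi-layer raster grid with a shared validity mask.

    Parameters
    ----------
    codes : list of str
        Variable code per layer, e.g. ``["bio1", ..., "bio19"]``.
    values : ndarray of shape (n_layers, nrows, ncols)
        Cell values; ``NaN`` marks nodata.  On construction the nodata mask is
        unioned across layers: a cell NaN in any layer becomes NaN in all.
    x0, y0 : float
        Longitude of the west edge and latitude of the north edge of the grid
        (the north-west corner).
    cellsize : float
        Cell size in decimal degrees (square cells); must be positive.
    units : list of str, optional
        Unit string per layer (informational).
    """

    codes: list[str]
    values: np.ndarray
    x0: float
    y0: float
    cellsize: float
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (n_layers, nrows, ncols) array")
        if len(self.codes) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.codes)} codes for {self.values.shape[0]} layers"
            )
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if not self.units:
            self.units = [""] * len(self.codes)
        # union of per-layer nodata becomes the shared mask
        invalid = np.isnan(self.values).any(axis=0)
        self.values[:, invalid] = np.nan

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell is invalid in any layer."""
        return np.isnan(self.values[0])

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def point_to_cell(self, lon, lat):
        """Map points to (row, col); the single point-in-cell authority.

        Cells are half-open: ``[x0+c*res, x0+(c+1)*res)`` in longitude and
        ``(y0-(r+1)*res, y0-r*res]`` in latitude.  Points outside the grid get
        row/col of -1.  Accepts scalars or arrays.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x0) / self.cellsize).astype(int)
        row = np.floor((self.y0 - lat) / self.cellsize).astype(int)
        # top edge of row r (lat == y0 - r*res) belongs to row r, handled by
        # floor; the grid's own north edge (lat == y0) maps to row 0:
        row = np.where(lat == self.y0, 0, row)
        nrows, ncols = self.shape
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_center(self, row, col):
        """Longitude/latitude of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x0 + (col + 0.5) * self.cellsize
        lat = self.y0 - (row + 0.5) * self.cellsize
        if row.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def valid_cells(self) -> np.ndarray:
        """(n_valid, 2) array of row, col indices of valid cells, row-major."""
        return np.argwhere(self.valid_mask)

    # -- access -------------------------------------------------------------

    def layer(self, code: str) -> np.ndarray:
        try:
            return self.values[self.codes.index(code)]
        except ValueError:
            raise KeyError(f"no layer with code {code!r}") from None

    def subset(self, codes: Sequence[str]) -> "ClimateStack":
        """A stack restricted to the named layers, in the given order."""
        idx = [self.codes.index(c) if c in self.codes else self._missing(c) for c in codes]
        return ClimateStack(
            codes=list(codes),
            values=self.values[idx].copy(),
            x0=self.x0,
            y0=self.y0,
            cellsize=self.cellsize,
            units=[self.units[i] for i in idx],
        )

    def _missing(self, code: str):
        raise KeyError(f"no layer with code {code!r}")

    def blank_grid(self) -> np.ndarray:
        """An all-NaN grid matching this stack's shape."""
        return np.full(self.shape, np.nan)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (grid, x0, y0, cellsize).

    ``grid`` has NaN at nodata; (x0, y0) is the north-west corner.
    """
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {grid.shape}, header says ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid[grid == nodata] = np.nan
    cs = header["cellsize"]
    x0 = header["xllcorner"]
    y0 = header["yllcorner"] + nrows * cs
    return grid, x0, y0, cs


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_ascii_grid(grid: np.ndarray, x0: float, y0: float, cellsize: float,
                     path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a 2-D grid as an ESRI ASCII grid (NaN -> the nodata value)."""
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(x0)!r}\n")
        fh.write(f"yllcorner {float(y0 - nrows * cellsize)!r}\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, geographic CRS) via tifffile tags
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GTModelType=geographic, GTRasterType=PixelIsArea, GeographicType=WGS84
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_geotiff(grid: np.ndarray, x0: float, y0: float, cellsize: float,
                  path, nodata: float = DEFAULT_NODATA) -> None:
    import tifffile

    grid = np.asarray(grid, dtype=np.float64)
    out = np.where(np.isnan(grid), nodata, grid)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cellsize, cellsize, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, float, float, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError:
            raise ValueError(f"{path}: not a georeferenced TIFF") from None
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path}: non-square cells are not supported")
        x0, y0 = float(tie[3]), float(tie[4])
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    grid[grid == nodata] = np.nan
    return grid, x0, y0, float(sx)


# ---------------------------------------------------------------------------
# stack-level operations
# ---------------------------------------------------------------------------

def _read_any(path) -> tuple[np.ndarray, float, float, float]:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return read_geotiff(path)
    return read_ascii_grid(path)


def read_raster_stack(paths: Sequence, codes: Sequence[str]) -> ClimateStack:
    """Read aligned single-band rasters (ASCII grid or GeoTIFF) into a stack.

    Layer order follows the input order.  Any geometric mismatch (shape,
    origin or cell size) raises :class:`AlignmentError` naming the file.
    """
    if len(paths) != len(codes):
        raise ValueError("paths and codes must have equal length")
    if not paths:
        raise ValueError("at least one raster is required")
    grids = []
    geo = None
    for path in paths:
        grid, x0, y0, cs = _read_any(path)
        if geo is None:
            geo = (grid.shape, x0, y0, cs)
        else:
            shape0, gx0, gy0, gcs = geo
            same = (
                grid.shape == shape0
                and math.isclose(x0, gx0, abs_tol=1e-9)
                and math.isclose(y0, gy0, abs_tol=1e-9)
                and math.isclose(cs, gcs, rel_tol=1e-9)
            )
            if not same:
                raise AlignmentError(
                    f"{path}: grid (shape={grid.shape}, origin=({x0}, {y0}), "
                    f"cellsize={cs}) does not match the first raster "
                    f"(shape={shape0}, origin=({gx0}, {gy0}), cellsize={gcs})"
                )
        grids.append(grid)
    shape0, x0, y0, cs = geo
    return ClimateStack(list(codes), np.stack(grids), x0, y0, cs)


def write_raster(grid: np.ndarray, stack: ClimateStack, path,
                 nodata: float = DEFAULT_NODATA) -> None:
    """Write a grid on the stack's geometry; format chosen by file extension."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != stack.shape:
        raise ValueError(f"grid shape {grid.shape} != stack shape {stack.shape}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        write_geotiff(grid, stack.x0, stack.y0, stack.cellsize, path, nodata)
    else:
        write_ascii_grid(grid, stack.x0, stack.y0, stack.cellsize, path, nodata)


def extract_values(stack: ClimateStack, points: pd.DataFrame,
                   label: int | None = None) -> pd.DataFrame:
    """Build a sample matrix: one row per point, one column per layer.

    Parameters
    ----------
    stack : ClimateStack
    points : DataFrame with ``lon`` and ``lat`` columns
        Point order is preserved.  Points falling outside the grid or on
        nodata cells are dropped (the drop count is recorded in
        ``result.attrs["n_dropped_nodata"]``).
    label : 0 or 1, optional
        If given, a ``label`` column is added (1 presence, 0 background).
    """
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    row, col = stack.point_to_cell(lon, lat)
    inside = row >= 0
    valid = np.zeros(len(points), dtype=bool)
    valid[inside] = stack.valid_mask[row[inside], col[inside]]
    data = {"lon": lon[valid], "lat": lat[valid]}
    if label is not None:
        if label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        data["label"] = np.full(valid.sum(), label, dtype=int)
    for i, code in enumerate(stack.codes):
        data[code] = stack.values[i][row[valid], col[valid]]
    out = pd.DataFrame(data)
    out.attrs["n_dropped_nodata"] = int(len(points) - valid.sum())
    return out


def variable_columns(sample: pd.DataFrame) -> list[str]:
    """The climate-variable columns of a sample matrix (metadata excluded)."""
    return [c for c in sample.columns if c not in SAMPLE_META_COLUMNS]


def crop_stack(stack: ClimateStack, bbox: Sequence[float]) -> ClimateStack:
    """Crop to cells whose centers fall in ``bbox`` = (west, south, east, north).

    The box is half-open: west/south edges inclusive, east/north exclusive, so
    adjacent boxes tile the grid without overlap.  An empty intersection is an
    error.
    """
    west, south, east, north = map(float, bbox)
    nrows, ncols = stack.shape
    lon_c = stack.x0 + (np.arange(ncols) + 0.5) * stack.cellsize
    lat_c = stack.y0 - (np.arange(nrows) + 0.5) * stack.cellsize
    keep_c = (lon_c >= west) & (lon_c < east)
    keep_r = (lat_c >= south) & (lat_c < north)
    if not keep_c.any() or not keep_r.any():
        raise ValueError(f"bbox {bbox} does not intersect the stack extent")
    c0, c1 = np.flatnonzero(keep_c)[[0, -1]]
    r0, r1 = np.flatnonzero(keep_r)[[0, -1]]
    return ClimateStack(
        codes=list(stack.codes),
        values=stack.values[:, r0:r1 + 1, c0:c1 + 1].copy(),
        x0=stack.x0 + c0 * stack.cellsize,
        y0=stack.y0 - r0 * stack.cellsize,
        cellsize=stack.cellsize,
        units=list(stack.units),
    )
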