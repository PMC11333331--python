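"""Georeferenced raster grids, occurrence records, and value extraction.

Rasters are plain latitude/longitude grids (WGS84 decimal degrees) in the
cell-registered (lower-left *corner*) convention, row 0 = northernmost row,
exactly as the ESRI ASCII grid format lays them out.  All area and distance
computations in the package use a spherical Earth of radius 6371.0 km.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridFormatError, OutOfBoundsError

EARTH_RADIUS_KM = 6371.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class RasterGrid:
    """A single gridded environmental layer.

    Parameters
    ----------
    name : str
        Layer identifier, e.g. ``"bio6"``.
    xll, yll : float
        Lower-left *corner* of the grid in decimal degrees.
    cellsize : float
        Cell edge length in degrees (square cells).
    nodata : float
        Sentinel marking invalid cells.
    values : ndarray of shape (nrows, ncols)
        Row 0 is the northernmost row.
    """

    name: str
    xll: float
    yll: float
    cellsize: float
    nodata: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with nrows, ncols >= 1")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid measurement."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row's cell centers, row 0 (north) first."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(
            name=name or self.name,
            xll=self.xll,
            yll=self.yll,
            cellsize=self.cellsize,
            nodata=self.nodata,
            values=np.asarray(values, dtype=float),
        )


class EnvStack:
    """Ordered collection of :class:`RasterGrid` layers sharing one grid.

    The joint validity ``mask`` is the intersection of every layer's mask:
    a cell missing in any covariate is unusable as model background.
    """

    def __init__(self, layers: Iterable[RasterGrid]):
        layers = list(layers)
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        names = [g.name for g in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        ref = layers[0]
        for g in layers[1:]:
            if not g.same_grid(ref):
                raise ValueError(f"layer {g.name!r} is not on the same grid as {ref.name!r}")
        self.layers: dict[str, RasterGrid] = {g.name: g for g in layers}
        self.grid = ref

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def mask(self) -> np.ndarray:
        m = np.ones(self.grid.values.shape, dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    def subset(self, names: Sequence[str]) -> "EnvStack":
        return EnvStack([self.layers[n] for n in names])

    def table(self) -> pd.DataFrame:
        """Valid cells as a DataFrame (one row per cell, one column per layer)."""
        m = self.mask
        data = {name: g.values[m] for name, g in self.layers.items()}
        df = pd.DataFrame(data)
        rows, cols = np.nonzero(m)
        df.index = pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])
        return df

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of the valid cells, in ``table()`` row order."""
        m = self.mask
        rows, cols = np.nonzero(m)
        g = self.grid
        return g.lon_centers()[cols], g.lat_centers()[rows]


@dataclass
class OccurrenceSet:
    """Presence records for one species (WGS84 decimal degrees)."""

    species: str
    points: np.ndarray  # (n, 2) columns lon, lat
    duplicates_flagged: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) lon/lat pairs")
        lon, lat = self.points[:, 0], self.points[:, 1]
        if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside WGS84 bounds")
        _, inverse, counts = np.unique(
            self.points, axis=0, return_inverse=True, return_counts=True
        )
        self.duplicates_flagged = counts[inverse] > 1

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO
# ---------------------------------------------------------------------------

def read_esri_ascii(path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    Accepts header keys case-insensitively and converts the
    ``xllcenter``/``yllcenter`` dialect to the corner convention
    (corner = center − cellsize/2).
    """
    header: dict[str, float] = {}
    center_dialect = {"x": False, "y": False}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 7:
        raise GridFormatError(f"{path}: expected 6 header lines plus data")
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise GridFormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        key = parts[0].lower()
        try:
            val = float(parts[1])
        except ValueError as exc:
            raise GridFormatError(
                f"{path}: non-numeric header value on line {i + 1}: {line!r}"
            ) from exc
        if key == "xllcenter":
            key, center_dialect["x"] = "xllcorner", True
        elif key == "yllcenter":
            key, center_dialect["y"] = "yllcorner", True
        header[key] = val
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path}: header missing keys {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    cellsize = header["cellsize"]
    xll, yll = header["xllcorner"], header["yllcorner"]
    if center_dialect["x"]:
        xll -= cellsize / 2
    if center_dialect["y"]:
        yll -= cellsize / 2

    data_lines = [ln for ln in lines[6:] if ln.strip()]
    if len(data_lines) != nrows:
        raise GridFormatError(
            f"{path}: expected {nrows} data rows, found {len(data_lines)}"
        )
    rows = []
    for r, ln in enumerate(data_lines):
        vals = ln.split()
        if len(vals) != ncols:
            raise GridFormatError(
                f"{path}: row {r} has {len(vals)} values, expected {ncols}"
            )
        rows.append([float(v) for v in vals])
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return RasterGrid(
        name=name,
        xll=xll,
        yll=yll,
        cellsize=cellsize,
        nodata=header["nodata_value"],
        values=np.array(rows, dtype=float),
    )


def write_esri_ascii(grid: RasterGrid, path, decimals: int = 6) -> None:
    """Write a grid as an ESRI ASCII file (6-line header, north row first)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_fmt(grid.xll, decimals)}\n")
        fh.write(f"yllcorner {_fmt(grid.yll, decimals)}\n")
        fh.write(f"cellsize {_fmt(grid.cellsize, decimals)}\n")
        fh.write(f"NODATA_value {_fmt(grid.nodata, decimals)}\n")
        for row in grid.values:
            fh.write(" ".join(_fmt(v, decimals) for v in row) + "\n")


def _fmt(v: float, decimals: int) -> str:
    s = f"{v:.{decimals}f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def read_geotiff(path, name: str | None = None, nodata: float = -9999.0) -> RasterGrid:
    """Minimal GeoTIFF reader for plain lat/lon rasters (convenience adapter).

    Parses only the ModelPixelScale and ModelTiepoint tags for georeferencing
    and GDAL_NODATA for the sentinel; anything fancier (projections, rotation)
    is out of scope — inputs must already be geographic grids.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            scale = tags["ModelPixelScaleTag"].value
            tie = tags["ModelTiepointTag"].value
        except KeyError as exc:
            raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        if "GDAL_NODATA" in tags:
            nodata = float(str(tags["GDAL_NODATA"].value).strip("\x00 "))
    sx, sy = float(scale[0]), float(scale[1])
    if not np.isclose(sx, sy):
        raise GridFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster (i, j) = (0, 0) to the top-left corner (x, y)
    x0, y_top = float(tie[3]), float(tie[4])
    nrows, ncols = values.shape
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return RasterGrid(
        name=name,
        xll=x0,
        yll=y_top - nrows * sy,
        cellsize=sx,
        nodata=nodata,
        values=values,
    )


# ---------------------------------------------------------------------------
# Occurrence CSV IO (the MaxEnt "samples" dialect)
# ---------------------------------------------------------------------------

def read_occurrences(path) -> OccurrenceSet:
    """Read a ``species,longitude,latitude`` CSV of presence records."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("species", "longitude", "latitude"):
        if need not in cols:
            raise GridFormatError(f"{path}: occurrence CSV missing column {need!r}")
    species = str(df[cols["species"]].iloc[0])
    pts = df[[cols["longitude"], cols["latitude"]]].to_numpy(dtype=float)
    return OccurrenceSet(species=species, points=pts)


def write_occurrences(occ: OccurrenceSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "longitude", "latitude"])
        for lon, lat in occ.points:
            w.writerow([occ.species, repr(float(lon)), repr(float(lat))])


# ---------------------------------------------------------------------------
# Extraction & geometry
# ---------------------------------------------------------------------------

def _cell_indices(grid: RasterGrid, lon: np.ndarray, lat: np.ndarray):
    col = np.floor((lon - grid.xll) / grid.cellsize).astype(int)
    row_from_bottom = np.floor((lat - grid.yll) / grid.cellsize).astype(int)
    row = grid.nrows - 1 - row_from_bottom
    return row, col


def extract_values(
    stack: EnvStack, points: np.ndarray, method: str = "nearest"
) -> pd.DataFrame:
    """Extract layer values at (lon, lat) points.

    Returns one row per point with a column per layer plus ``has_nodata``
    marking points whose extraction touched an invalid cell (flagged, never
    silently dropped).
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    g = stack.grid
    lon, lat = points[:, 0], points[:, 1]
    x_max = g.xll + g.ncols * g.cellsize
    y_max = g.yll + g.nrows * g.cellsize
    bad = (lon < g.xll) | (lon > x_max) | (lat < g.yll) | (lat > y_max)
    if np.any(bad):
        offenders = points[bad][:5].tolist()
        raise OutOfBoundsError(f"points outside grid extent: {offenders}")

    out = {}
    if method == "nearest":
        row, col = _cell_indices(g, lon, lat)
        row = np.clip(row, 0, g.nrows - 1)
        col = np.clip(col, 0, g.ncols - 1)
        flag = np.zeros(len(points), dtype=bool)
        for name, layer in stack.layers.items():
            vals = layer.values[row, col]
            invalid = ~layer.mask[row, col]
            vals = np.where(invalid, np.nan, vals)
            flag |= invalid
            out[name] = vals
    else:
        flag = np.zeros(len(points), dtype=bool)
        for name, layer in stack.layers.items():
            vals, inv = _bilinear(layer, lon, lat)
            flag |= inv
            out[name] = vals
    df = pd.DataFrame(out)
    df.insert(0, "longitude", lon)
    df.insert(1, "latitude", lat)
    df["has_nodata"] = flag
    return df


def _bilinear(layer: RasterGrid, lon: np.ndarray, lat: np.ndarray):
    g = layer
    # fractional position in units of cells, measured from the SW cell center
    fx = (lon - (g.xll + g.cellsize / 2)) / g.cellsize
    fy = (lat - (g.yll + g.cellsize / 2)) / g.cellsize
    x0 = np.clip(np.floor(fx).astype(int), 0, g.ncols - 2) if g.ncols > 1 else np.zeros(len(lon), int)
    y0 = np.clip(np.floor(fy).astype(int), 0, g.nrows - 2) if g.nrows > 1 else np.zeros(len(lat), int)
    tx = np.clip(fx - x0, 0.0, 1.0)
    ty = np.clip(fy - y0, 0.0, 1.0)
    r1 = g.nrows - 1 - y0          # southern row
    r0 = np.maximum(r1 - 1, 0)     # northern row
    c0, c1 = x0, np.minimum(x0 + 1, g.ncols - 1)
    v = g.values
    m = g.mask
    corners = [(r1, c0), (r1, c1), (r0, c0), (r0, c1)]
    weights = [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
    acc = np.zeros(len(lon))
    invalid = np.zeros(len(lon), dtype=bool)
    for (rr, cc), w in zip(corners, weights):
        acc += np.where(m[rr, cc], v[rr, cc], 0.0) * w
        invalid |= (~m[rr, cc]) & (w > 0)
    return np.where(invalid, np.nan, acc), invalid


def cell_area_km2(grid: RasterGrid, row: int) -> float:
    """Area in km² of one cell in the given row (latitude-corrected).

    area = (πR/180 · cellsize)² · cos(latitude of the row's cell centers),
    with a spherical Earth R = 6371.0 km.
    """
    if not 0 <= row < grid.nrows:
        raise IndexError(f"row {row} out of range [0, {grid.nrows})")
    lat = grid.lat_centers()[row]
    edge = np.pi * EARTH_RADIUS_KM / 180.0 * grid.cellsize
    return float(edge * edge * np.cos(np.radians(lat)))


def cell_area_grid(grid: RasterGrid) -> np.ndarray:
    """Per-cell areas (km²) broadcast across the full grid."""
    lat = grid.lat_centers()
    edge = np.pi * EARTH_RADIUS_KM / 180.0 * grid.cellsize
    per_row = edge * edge * np.cos(np.radians(lat))
    return np.repeat(per_row[:, None], grid.ncols, axis=1)
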