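"""Regular geographic grids and raster layers.

All layers in one analysis share a single :class:`GridSpec`: a cell-edge
registered, row-major grid anchored at its north-west corner, with square
cells in decimal degrees (WGS84 lon/lat).  Cell ``(r, c)`` covers the
half-open interval ``[edge, edge + resolution)`` on each axis, rows counted
southward from the top edge.

Rasters are read and written as ESRI ASCII grids (``.asc``) — a plain-text,
GDAL-compatible single-band format that preserves the grid geometry and the
nodata sentinel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Raster", "GridMismatchError", "read_ascii_grid", "write_ascii_grid"]


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis grid.

    Parameters
    ----------
    origin_lon, origin_lat
        Longitude of the west edge and latitude of the north edge of
        cell ``(0, 0)``.
    resolution
        Cell size in decimal degrees (square cells).
    nrows, ncols
        Grid extent.
    """

    origin_lon: float
    origin_lat: float
    resolution: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"extent must be positive, got {self.nrows}x{self.ncols}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_deg2(self) -> float:
        return self.resolution * self.resolution

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the full grid."""
        return (
            self.origin_lon,
            self.origin_lat - self.nrows * self.resolution,
            self.origin_lon + self.ncols * self.resolution,
            self.origin_lat,
        )

    def cell_of(self, lon, lat):
        """Row/col of the cell whose half-open extent contains the point.

        Points on the top or west edge of a cell belong to it; points off
        the grid get index -1 in the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.resolution).astype(np.int64)
        row = np.floor((self.origin_lat - lat) / self.resolution).astype(np.int64)
        # lat exactly on the north edge of the grid belongs to row 0
        row = np.where(
            np.isclose(lat, self.origin_lat, rtol=0.0, atol=0.0), np.maximum(row, 0), row
        )
        bad = (col < 0) | (col >= self.ncols)
        col = np.where(bad, -1, col)
        bad = (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        if col.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_center(self, row, col):
        """(lon, lat) of the centre of cell ``(row, col)``."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.origin_lon + (col + 0.5) * self.resolution
        lat = self.origin_lat - (row + 0.5) * self.resolution
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (nrows, ncols) arrays of cell-centre lon and lat."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lon = self.origin_lon + (cols + 0.5) * self.resolution
        lat = self.origin_lat - (rows + 0.5) * self.resolution
        return np.broadcast_to(lon, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            lat[:, None], (self.nrows, self.ncols)
        ).copy()

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of one cell."""
        west = self.origin_lon + col * self.resolution
        north = self.origin_lat - row * self.resolution
        return (west, north - self.resolution, west + self.resolution, north)


@dataclass
class Raster:
    """One band on a :class:`GridSpec`.

    ``values`` is a (nrows, ncols) array; cells equal to ``nodata`` (or NaN
    for float rasters with ``nodata=nan``) carry no observation.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def same_grid(self, other: "Raster | GridSpec", *, names: tuple[str, str] = ("a", "b")) -> None:
        other_grid = other.grid if isinstance(other, Raster) else other
        if other_grid != self.grid:
            raise GridMismatchError(
                f"grid mismatch between {names[0]} ({self.grid}) and {names[1]} ({other_grid}); "
                "use the regrid command for intentional resampling"
            )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write one band as an ESRI ASCII grid (cell-edge registered)."""
    g = raster.grid
    yll = g.origin_lat - g.nrows * g.resolution
    vals = raster.values
    if np.isnan(raster.nodata):
        vals = np.where(np.isnan(vals), -9999.0, vals)
        nodata_repr = -9999
    else:
        nodata_repr = raster.nodata
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.origin_lon!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.resolution!r}\n"
        f"NODATA_value {nodata_repr}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if np.issubdtype(np.asarray(vals).dtype, np.integer):
            np.savetxt(fh, vals, fmt="%d")
        else:
            np.savetxt(fh, vals, fmt="%.17g")  # exact float64 round-trip


def read_ascii_grid(path: str | Path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid back into a :class:`Raster`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=dtype, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    res = header["cellsize"]
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * res,
        resolution=res,
        nrows=nrows,
        ncols=ncols,
    )
    nodata = header.get("nodata_value", -9999.0)
    return Raster(grid=grid, values=values, nodata=dtype(nodata))
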