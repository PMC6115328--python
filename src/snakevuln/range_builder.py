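"""Contemporary species ranges from EORs, record buffers, and the MESS.

Valid (MESS-positive) occurrence records outside a species' expert-opinion
range (EOR) amend it: each such record is buffered by a fixed angular
radius (default 0.898 deg, about 100 km at the equator, absorbing both
animal movement and geopositioning error), the buffered discs are masked
to cells of environmental interpolation, and the remainder is merged with
the EOR.  The result always contains the EOR; species with no
MESS-positive outside records keep their EOR unchanged.  Ranges are then
rasterized onto the shared analysis grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import box, Point

from .grid import GridSpec, Raster
from .mess import MessSurface
from .registry import OccurrenceRecord

__all__ = [
    "EORMap",
    "RangeRaster",
    "select_outside_records",
    "buffer_records",
    "build_contemporary_range",
    "rasterize_range",
    "split_antimeridian",
]

logger = logging.getLogger(__name__)

PRESENT, ABSENT, NODATA = 1, 0, 255


@dataclass
class EORMap:
    """Expert-opinion range polygon(s) for one species, WGS84 degrees."""

    species_id: str
    geometry: shapely.Geometry

    def __post_init__(self) -> None:
        if self.geometry.is_empty:
            raise ValueError(f"{self.species_id}: EOR geometry is empty")
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)
            logger.info("%s: EOR geometry repaired with make_valid", self.species_id)


@dataclass
class RangeRaster:
    """Per-cell presence of one species on the shared grid (1/0/255)."""

    species_id: str
    grid: GridSpec
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != self.grid.shape:
            raise ValueError("presence shape does not match grid")

    def to_raster(self) -> Raster:
        return Raster(self.grid, self.presence, nodata=NODATA)


def select_outside_records(
    records: list[OccurrenceRecord], eor: EORMap
) -> list[OccurrenceRecord]:
    """Records strictly outside the EOR (boundary points count as inside)."""
    return [
        r
        for r in records
        if not shapely.intersects(eor.geometry, Point(r.lon, r.lat))
    ]


def buffer_records(
    points: list[OccurrenceRecord] | list[Point],
    radius_deg: float,
    *,
    segments: int = 64,
) -> shapely.Geometry:
    """Union of planar discs of ``radius_deg`` around each point.

    Discs are drawn in lon/lat degree space (the radius is specified as an
    angle, not a geodesic distance) and approximated by ``segments``-gon
    polygons.  Discs crossing the antimeridian are split at +-180.
    """
    if radius_deg <= 0:
        raise ValueError("buffer radius must be positive")
    geoms = []
    for p in points:
        pt = p if isinstance(p, Point) else Point(p.lon, p.lat)
        geoms.append(pt.buffer(radius_deg, quad_segs=segments // 4))
    if not geoms:
        return shapely.GeometryCollection()
    return split_antimeridian(shapely.union_all(geoms))


def split_antimeridian(geom: shapely.Geometry) -> shapely.Geometry:
    """Wrap parts of a geometry that overflow lon = +-180 back into range."""
    minx, _, maxx, _ = shapely.bounds(geom)
    if minx >= -180.0 and maxx <= 180.0:
        return geom
    world = box(-180.0, -90.0, 180.0, 90.0)
    parts = [geom.intersection(world)]
    if maxx > 180.0:
        east = geom.intersection(box(180.0, -90.0, maxx + 1.0, 90.0))
        parts.append(affinity.translate(east, xoff=-360.0))
    if minx < -180.0:
        west = geom.intersection(box(minx - 1.0, -90.0, -180.0, 90.0))
        parts.append(affinity.translate(west, xoff=360.0))
    return shapely.union_all([p for p in parts if not p.is_empty])


def interpolation_cells_polygon(
    surface: MessSurface, within_bounds: tuple[float, float, float, float] | None = None
) -> shapely.Geometry:
    """Union of interpolation cells as square polygons on the surface grid.

    ``within_bounds`` restricts the conversion to cells intersecting the
    given (minx, miny, maxx, maxy) window — the mask is only consumed where
    the buffered records are.
    """
    grid = surface.grid
    mask = surface.interpolation_mask
    rows, cols = np.nonzero(mask)
    if within_bounds is not None:
        minx, miny, maxx, maxy = within_bounds
        lon_w = grid.origin_lon + cols * grid.resolution
        lat_n = grid.origin_lat - rows * grid.resolution
        keep = (
            (lon_w + grid.resolution >= minx)
            & (lon_w <= maxx)
            & (lat_n >= miny)
            & (lat_n - grid.resolution <= maxy)
        )
        rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        return shapely.GeometryCollection()
    boxes = [box(*grid.cell_box(int(r), int(c))) for r, c in zip(rows, cols)]
    return shapely.union_all(boxes)


def build_contemporary_range(
    eor: EORMap,
    buffered: shapely.Geometry,
    surface: MessSurface | None,
) -> shapely.Geometry:
    """EOR merged with the MESS-masked buffered records.

    Returns ``EOR ∪ (buffered ∩ interpolation cells)``; with no buffered
    geometry (or no surface) the EOR is returned unchanged, so the result
    is always a superset of the EOR.
    """
    if buffered is None or buffered.is_empty:
        return eor.geometry
    if surface is None:
        raise ValueError("a MESS surface is required to mask buffered records")
    mask_poly = interpolation_cells_polygon(surface, within_bounds=shapely.bounds(buffered))
    masked = buffered.intersection(mask_poly)
    if masked.is_empty:
        return eor.geometry
    return shapely.union_all([eor.geometry, masked])


def rasterize_range(
    geometry: shapely.Geometry,
    grid: GridSpec,
    species_id: str = "",
    *,
    all_touched: bool = False,
) -> RangeRaster:
    """Burn a range geometry onto the analysis grid.

    Default rule: a cell is present iff its centre lies in the geometry
    (boundary inclusive).  With ``all_touched`` a cell is present iff its
    square intersects the geometry.
    """
    presence = np.zeros(grid.shape, dtype=np.uint8)
    if geometry is None or geometry.is_empty:
        return RangeRaster(species_id, grid, presence)
    if all_touched:
        minx, miny, maxx, maxy = shapely.bounds(geometry)
        r0, c0 = grid.cell_of(minx, maxy)
        r1, c1 = grid.cell_of(maxx, miny)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1 = grid.nrows - 1 if r1 < 0 else r1
        c1 = grid.ncols - 1 if c1 < 0 else c1
        shapely.prepare(geometry)
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                if shapely.intersects(geometry, box(*grid.cell_box(r, c))):
                    presence[r, c] = PRESENT
        return RangeRaster(species_id, grid, presence)
    lon, lat = grid.center_coords()
    shapely.prepare(geometry)
    inside = shapely.intersects_xy(geometry, lon.ravel(), lat.ravel()).reshape(grid.shape)
    presence[inside] = PRESENT
    return RangeRaster(species_id, grid, presence)
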