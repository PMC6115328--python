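"""Health-system layers: HAQ deciles, travel-time remoteness, delay scaling.

The Healthcare Access and Quality (HAQ) Index is a 0-100 composite of
mortality amenable to health care.  Countries are ranked ascending and
split into ten equally sized groups (decile 1 = lowest quality); the
per-decile value thresholds derived from countries then place subnational
units, which never participate in threshold construction.  Travel time to
the nearest population centre of more than 50 000 people proxies access
to care; "more than h hours away" is read strictly.  Treatment delay is
converted to excess mortality linearly at 1.01 percentage points per hour
(a cohort-derived statistic; its linear extrapolation far beyond the
source cohort's delays is an assumption flagged in output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely

from .grid import GridSpec, Raster

__all__ = [
    "HealthUnitRecord",
    "DecileThresholds",
    "assign_haq_deciles",
    "assign_subnational_deciles",
    "rasterize_deciles",
    "classify_travel_time",
    "delay_mortality_scaling",
]

DECILE_NODATA = 0  # deciles are 1..10; 0 marks cells outside all units


@dataclass
class HealthUnitRecord:
    """A national or subnational unit with an HAQ value (0-100 scale)."""

    unit_id: str
    haq_value: float
    level: str = "national"  # "national" | "subnational"
    parent_country: str | None = None
    decile: int | None = None

    def __post_init__(self) -> None:
        if self.level not in ("national", "subnational"):
            raise ValueError(f"{self.unit_id}: level must be national or subnational")
        if not 0.0 <= self.haq_value <= 100.0:
            raise ValueError(f"{self.unit_id}: HAQ value {self.haq_value} outside 0-100")


@dataclass
class DecileThresholds:
    """Upper HAQ value of each national decile (index 0 = decile 1)."""

    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.upper) != 10:
            raise ValueError("exactly 10 decile thresholds required")

    def decile_of(self, value: float) -> int:
        """Decile whose value interval (lower, upper] contains ``value``.

        Values at or below the decile-1 upper bound map to 1; values
        above the decile-10 bound clamp to 10.
        """
        for d in range(10):
            if value <= self.upper[d]:
                return d + 1
        return 10


def assign_haq_deciles(
    countries: list[HealthUnitRecord],
) -> tuple[list[HealthUnitRecord], DecileThresholds]:
    """Rank countries by HAQ value and cut into ten equally sized groups.

    The country at ascending rank r (1-based) of N receives decile
    ``floor(10*(r-1)/N) + 1``, so group sizes differ by at most one and
    every decile is populated for N >= 10.  Ties spanning a boundary are
    broken by unit_id order for determinism.
    """
    nationals = [u for u in countries if u.level == "national"]
    if len(nationals) < 10:
        raise ValueError(f"decile construction needs >= 10 countries, got {len(nationals)}")
    n = len(nationals)
    ranked = sorted(nationals, key=lambda u: (u.haq_value, u.unit_id))
    out = []
    upper = [-np.inf] * 10
    for r, unit in enumerate(ranked):
        d = (10 * r) // n + 1
        out.append(replace(unit, decile=d))
        upper[d - 1] = max(upper[d - 1], unit.haq_value)
    # backfill any decile that ended up empty (only possible for n < 10,
    # excluded above, but keep the thresholds monotone regardless)
    for d in range(1, 10):
        if not np.isfinite(upper[d]):
            upper[d] = upper[d - 1]
    return out, DecileThresholds(tuple(float(u) for u in upper))


def assign_subnational_deciles(
    subnationals: list[HealthUnitRecord], thresholds: DecileThresholds
) -> list[HealthUnitRecord]:
    """Place subnational units into the nationally derived deciles by value."""
    return [replace(u, decile=thresholds.decile_of(u.haq_value)) for u in subnationals]


def rasterize_deciles(
    units: list[HealthUnitRecord],
    polygons: dict[str, shapely.Geometry],
    grid: GridSpec,
) -> Raster:
    """Per-cell decile of the unit containing the cell centre.

    Units are burnt in list order and a cell keeps its first assignment,
    so centres on shared borders go to the unit listed first.  Cells
    outside every polygon are nodata (0).
    """
    decile_by_unit = {u.unit_id: u.decile for u in units}
    out = np.zeros(grid.shape, dtype=np.int16)
    lon, lat = grid.center_coords()
    unassigned = np.ones(grid.shape, dtype=bool)
    for u in units:
        geom = polygons.get(u.unit_id)
        if geom is None:
            raise KeyError(f"no polygon for unit {u.unit_id}")
        if u.decile is None:
            raise ValueError(f"unit {u.unit_id} has no decile assigned")
        shapely.prepare(geom)
        hit = shapely.intersects_xy(geom, lon.ravel(), lat.ravel()).reshape(grid.shape)
        take = hit & unassigned
        out[take] = u.decile
        unassigned &= ~take
    return Raster(grid, out, nodata=DECILE_NODATA)


def classify_travel_time(raster: Raster, threshold_min: float) -> np.ndarray:
    """Boolean remoteness mask: travel time strictly greater than threshold.

    Nodata cells are never remote (no evidence of remoteness).
    """
    if threshold_min <= 0:
        raise ValueError("travel-time threshold must be positive")
    with np.errstate(invalid="ignore"):
        return np.asarray(raster.valid & (raster.values > threshold_min))


def delay_mortality_scaling(delay_hours, slope_pct_per_hour: float = 1.01):
    """Excess mortality (percentage points) from a treatment delay.

    Linear in the delay: ``slope * hours``.  The default slope of 1.01
    percentage points per hour comes from a Nigerian cohort of envenoming
    cases relating time-to-antivenom to mortality.
    """
    delay_hours = np.asarray(delay_hours, dtype=float)
    if np.any(delay_hours < 0):
        raise ValueError("delay must be nonnegative")
    out = slope_pct_per_hour * delay_hours
    return float(out) if out.ndim == 0 else out
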