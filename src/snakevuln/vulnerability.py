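"""Vulnerability masks and population enumeration.

A cell is *vulnerable* when it lies within the range of at least one
snake species (optionally only species with no listed antivenom), is more
than a travel-time threshold from the nearest major population centre,
and falls in a low-quality HAQ decile.  Gridded population is summed over
vulnerable cells and aggregated to second-level administrative units,
countries, and HAQ deciles.  Cell-to-unit assignment is by cell centre;
masked population on cells outside every admin polygon is reported in an
explicit "unassigned" bucket rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import GridSpec, GridMismatchError, Raster
from .raster_stack import RichnessRaster

__all__ = [
    "AdminUnit",
    "vulnerability_mask",
    "enumerate_population",
    "decile_table",
    "population_within_range",
    "rasterize_admin_units",
]

UNASSIGNED = "unassigned"


@dataclass
class AdminUnit:
    """A second-level administrative unit keyed to its country."""

    unit_id: str
    country: str
    geometry: shapely.Geometry
    decile: int | None = None


def _check_grids(grid: GridSpec, *layers) -> None:
    for layer in layers:
        g = layer.grid if hasattr(layer, "grid") else None
        if g is not None and g != grid:
            raise GridMismatchError("all vulnerability layers must share one grid")


def vulnerability_mask(
    richness: RichnessRaster,
    travel_mask: np.ndarray,
    decile_raster: Raster,
    deciles: frozenset[int] | set[int],
) -> np.ndarray:
    """Cells with >= 1 species in the stratum, remote, and in the deciles.

    Pass the no-therapy richness layer as ``richness`` to restrict to
    species lacking antivenom.
    """
    _check_grids(richness.grid, decile_raster)
    if travel_mask.shape != richness.grid.shape:
        raise GridMismatchError("travel mask shape does not match grid")
    in_range = richness.valid & (richness.counts >= 1)
    in_decile = np.isin(decile_raster.values, list(deciles))
    return in_range & np.asarray(travel_mask, dtype=bool) & in_decile


def rasterize_admin_units(units: list[AdminUnit], grid: GridSpec) -> np.ndarray:
    """Index raster of admin units (first listed wins on shared borders).

    Returns int array of indices into ``units``; -1 where no unit
    contains the cell centre.
    """
    out = np.full(grid.shape, -1, dtype=np.int32)
    lon, lat = grid.center_coords()
    unassigned = np.ones(grid.shape, dtype=bool)
    for i, unit in enumerate(units):
        shapely.prepare(unit.geometry)
        hit = shapely.intersects_xy(unit.geometry, lon.ravel(), lat.ravel()).reshape(grid.shape)
        take = hit & unassigned
        out[take] = i
        unassigned &= ~take
    return out


def enumerate_population(
    mask: np.ndarray,
    population: Raster,
    units: list[AdminUnit],
    *,
    unit_index: np.ndarray | None = None,
    richness: RichnessRaster | None = None,
    no_therapy_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sum population over masked cells, per admin-2 unit.

    Returns one row per unit (plus an ``unassigned`` row when masked
    population falls outside all polygons) with columns
    ``admin_unit, country, decile, population_vulnerable,
    population_vulnerable_no_therapy, population_in_range,
    population_total, percent_of_unit_population``.  Populations are kept
    as reals; round only when writing reports.
    """
    grid = population.grid
    if mask.shape != grid.shape:
        raise GridMismatchError("mask shape does not match population grid")
    if unit_index is None:
        unit_index = rasterize_admin_units(units, grid)
    pop = np.where(population.valid, population.values.astype(float), 0.0)
    rows = []
    keys = list(range(len(units))) + [-1]
    for i in keys:
        cells = unit_index == i
        if i == -1 and not np.any(cells & mask):
            continue
        unit = units[i] if i >= 0 else None
        vul = float(pop[cells & mask].sum())
        row = {
            "admin_unit": unit.unit_id if unit else UNASSIGNED,
            "country": unit.country if unit else UNASSIGNED,
            "decile": unit.decile if unit else None,
            "population_vulnerable": vul,
            "population_total": float(pop[cells].sum()),
        }
        if no_therapy_mask is not None:
            row["population_vulnerable_no_therapy"] = float(
                pop[cells & mask & no_therapy_mask].sum()
            )
        if richness is not None:
            in_range = richness.valid & (richness.counts >= 1)
            row["population_in_range"] = float(pop[cells & in_range].sum())
        row["percent_of_unit_population"] = (
            100.0 * vul / row["population_total"] if row["population_total"] > 0 else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows)


def decile_table(report: pd.DataFrame, value_col: str = "population_vulnerable") -> pd.DataFrame:
    """Country-by-decile matrix of vulnerable population with totals.

    Each country contributes to exactly one decile column (its own);
    countries with zero vulnerable population everywhere are dropped from
    the matrix, mirroring the blank rows of published tables.  A ``Total``
    row holds per-decile column sums; the grand total is the sum of that
    row.
    """
    df = report[report["country"] != UNASSIGNED].copy()
    if df.empty:
        cols = [f"decile_{d}" for d in range(1, 11)]
        out = pd.DataFrame(columns=cols)
        out.loc["Total"] = 0.0
        return out
    grouped = (
        df.groupby(["country", "decile"], dropna=False)[value_col].sum().reset_index()
    )
    wide = grouped.pivot_table(
        index="country", columns="decile", values=value_col, aggfunc="sum", fill_value=0.0
    )
    wide = wide.reindex(columns=range(1, 11), fill_value=0.0)
    wide.columns = [f"decile_{int(d)}" for d in wide.columns]
    wide = wide.loc[wide.sum(axis=1) > 0]
    wide.loc["Total"] = wide.sum(axis=0)
    return wide


def grand_total(table: pd.DataFrame) -> float:
    """Sum of the Total row of a decile table."""
    return float(table.loc["Total"].sum())


def population_within_range(
    richness: RichnessRaster,
    population: Raster,
    *,
    travel_mask: np.ndarray | None = None,
    decile_raster: Raster | None = None,
    deciles: frozenset[int] | set[int] | None = None,
) -> float:
    """Population on cells with >= 1 species, under optional filters.

    Filters are conjunctive, so adding one can only decrease the total.
    """
    _check_grids(richness.grid, population)
    sel = richness.valid & (richness.counts >= 1)
    if travel_mask is not None:
        sel &= np.asarray(travel_mask, dtype=bool)
    if decile_raster is not None:
        if deciles is None:
            raise ValueError("deciles must be given with a decile raster")
        _check_grids(richness.grid, decile_raster)
        sel &= np.isin(decile_raster.values, list(deciles))
    pop = np.where(population.valid, population.values.astype(float), 0.0)
    return float(pop[sel].sum())
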