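"""Richness layers: per-cell counts of overlapping species ranges.

Per-species presence rasters are stacked by summing, producing composite
layers for all species, WHO category 1 only, and category 2 only, plus
the same three restricted to species with no listed antivenom.  A cell is
nodata only where every contributing raster is nodata; a species that is
nodata at a cell with other valid input is counted absent there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .grid import GridSpec, GridMismatchError, Raster
from .range_builder import RangeRaster, PRESENT, NODATA
from .registry import SpeciesRecord

__all__ = ["RichnessRaster", "stack_ranges", "composite_layers", "no_therapy_layers"]

STRATA = ("all", "category1", "category2", "no_antivenom_all", "no_antivenom_cat1", "no_antivenom_cat2")


@dataclass
class RichnessRaster:
    """Per-cell species count for one stratum (int16; -1 = nodata)."""

    grid: GridSpec
    counts: np.ndarray
    stratum: str = "all"
    nodata: int = -1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int16)
        if self.counts.shape != self.grid.shape:
            raise GridMismatchError("counts shape does not match grid")

    @property
    def valid(self) -> np.ndarray:
        return self.counts != self.nodata

    def to_raster(self) -> Raster:
        return Raster(self.grid, self.counts, nodata=self.nodata)

    def max_richness(self) -> int:
        v = self.counts[self.valid]
        return int(v.max()) if v.size else 0


def stack_ranges(
    rasters: Iterable[RangeRaster],
    species: Iterable[SpeciesRecord] | None = None,
    predicate: Callable[[SpeciesRecord], bool] | None = None,
    stratum: str = "all",
) -> RichnessRaster:
    """Sum presence over the species selected by ``predicate``.

    ``species`` (parallel to ``rasters``) is only needed when a predicate
    filters on registry attributes.  All rasters must share one grid.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no rasters to stack")
    grid = rasters[0].grid
    if species is None:
        species = [None] * len(rasters)
    else:
        species = list(species)
        if len(species) != len(rasters):
            raise ValueError("species list must parallel the raster list")
    counts = np.zeros(grid.shape, dtype=np.int16)
    any_valid = np.zeros(grid.shape, dtype=bool)
    for sp, rr in zip(species, rasters):
        if rr.grid != grid:
            raise GridMismatchError(
                f"raster for {rr.species_id} is not on the shared analysis grid"
            )
        valid = rr.presence != NODATA
        any_valid |= valid
        if predicate is not None and not predicate(sp):
            continue
        counts += (rr.presence == PRESENT).astype(np.int16)
    counts[~any_valid] = -1
    return RichnessRaster(grid, counts, stratum=stratum)


def composite_layers(
    rasters: list[RangeRaster], registry: list[SpeciesRecord]
) -> dict[str, RichnessRaster]:
    """The three composite richness layers: all, category 1, category 2."""
    return {
        "all": stack_ranges(rasters, registry, lambda s: True, "all"),
        "category1": stack_ranges(rasters, registry, lambda s: s.who_category == 1, "category1"),
        "category2": stack_ranges(rasters, registry, lambda s: s.who_category == 2, "category2"),
    }


def no_therapy_layers(
    rasters: list[RangeRaster], registry: list[SpeciesRecord]
) -> dict[str, RichnessRaster]:
    """Richness restricted to species with no listed antivenom, by category."""

    def no_av(s: SpeciesRecord) -> bool:
        return s.antivenom_available is False

    return {
        "no_antivenom_all": stack_ranges(rasters, registry, no_av, "no_antivenom_all"),
        "no_antivenom_cat1": stack_ranges(
            rasters, registry, lambda s: no_av(s) and s.who_category == 1, "no_antivenom_cat1"
        ),
        "no_antivenom_cat2": stack_ranges(
            rasters, registry, lambda s: no_av(s) and s.who_category == 2, "no_antivenom_cat2"
        ),
    }
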