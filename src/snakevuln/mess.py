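"""Multivariate environmental similarity surfaces (MESS).

A MESS scores how similar a cell's environment is to a *training sample*
of environments — here, the covariate values at a species' occurrence
records inside its expert-opinion range (EOR).  Per covariate, with
``f`` the percentage of training values strictly below the candidate
value ``v`` and ``lo``/``hi`` the training extremes, the similarity is

* ``f == 0``:        ``100 * (v - lo) / (hi - lo)``
* ``0 < f <= 50``:   ``2 * f``
* ``50 < f < 100``:  ``2 * (100 - f)``
* ``f == 100``:      ``100 * (hi - v) / (hi - lo)``

so the score is negative exactly when ``v`` falls outside the training
interval ``[lo, hi]``.  The surface value of a cell is the *minimum*
across covariates; cells at or above the configured threshold (default 0)
are environmental interpolation ("MESS-positive"), cells below it are
extrapolation.  Records landing on interpolation cells are treated as
valid evidence of occurrence beyond the EOR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely

from .config import AnalysisConfig
from .grid import GridSpec, Raster
from .registry import OccurrenceRecord

__all__ = [
    "CovariateStack",
    "TrainingSample",
    "MessSurface",
    "InsufficientTrainingError",
    "similarity_one",
    "similarity_vector",
    "extract_training",
    "mess_surface",
    "classify_records",
    "MESS_POSITIVE",
    "MESS_NEGATIVE",
    "NODATA_LABEL",
]

logger = logging.getLogger(__name__)

MESS_POSITIVE = "MESS-positive"
MESS_NEGATIVE = "MESS-negative"
NODATA_LABEL = "nodata"


class InsufficientTrainingError(ValueError):
    """Fewer than two usable training records: the MESS fit is refused
    and the species keeps its original EOR."""


@dataclass
class CovariateStack:
    """Named environmental covariate bands sharing one grid."""

    grid: GridSpec
    bands: dict[str, np.ndarray]
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        names = list(self.bands)
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        for name, arr in self.bands.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"band {name}: shape {arr.shape} != grid {self.grid.shape}")
            self.bands[name] = arr

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def valid_mask(self) -> np.ndarray:
        """Cells where every band has data (any nodata band voids the cell)."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for arr in self.bands.values():
            if np.isnan(self.nodata):
                mask &= ~np.isnan(arr)
            else:
                mask &= arr != self.nodata
        return mask

    def crop(self, bounds: tuple[float, float, float, float]) -> "CovariateStack":
        """Sub-stack covering ``(minx, miny, maxx, maxy)``, snapped outward
        to cell edges and clipped to the grid.  Cell centres of the crop
        coincide with parent-grid centres, so per-cell results agree."""
        g = self.grid
        minx, miny, maxx, maxy = bounds
        c0 = max(int(np.floor((minx - g.origin_lon) / g.resolution)), 0)
        c1 = min(int(np.ceil((maxx - g.origin_lon) / g.resolution)), g.ncols)
        r0 = max(int(np.floor((g.origin_lat - maxy) / g.resolution)), 0)
        r1 = min(int(np.ceil((g.origin_lat - miny) / g.resolution)), g.nrows)
        if c1 <= c0 or r1 <= r0:
            raise ValueError("crop window does not intersect the grid")
        sub = GridSpec(
            origin_lon=g.origin_lon + c0 * g.resolution,
            origin_lat=g.origin_lat - r0 * g.resolution,
            resolution=g.resolution,
            nrows=r1 - r0,
            ncols=c1 - c0,
        )
        return CovariateStack(
            sub, {k: v[r0:r1, c0:c1].copy() for k, v in self.bands.items()}, self.nodata
        )


@dataclass
class TrainingSample:
    """Covariate values at within-EOR record cells, with their envelope."""

    values: dict[str, np.ndarray]  # per band, sorted ascending
    n: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) != 1:
            raise ValueError("training vectors must have equal length across covariates")
        self.n = lengths.pop()
        if self.n < 2:
            raise InsufficientTrainingError(
                f"MESS fit needs >= 2 training records, got {self.n}"
            )
        self.values = {k: np.sort(np.asarray(v, dtype=float)) for k, v in self.values.items()}

    def envelope(self, band: str) -> tuple[float, float]:
        v = self.values[band]
        return float(v[0]), float(v[-1])


@dataclass
class MessSurface:
    """Per-cell minimum similarity and its threshold classification."""

    grid: GridSpec
    similarity: np.ndarray  # float, NaN = nodata
    threshold: float = 0.0

    @property
    def interpolation_mask(self) -> np.ndarray:
        """True where similarity >= threshold; False elsewhere incl. nodata."""
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(self.similarity), False, self.similarity >= self.threshold)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.similarity)

    def to_rasters(self) -> tuple[Raster, Raster]:
        """(similarity, mask) rasters for writing; mask nodata is 255."""
        sim = Raster(self.grid, self.similarity, nodata=float("nan"))
        mask = np.where(self.valid, self.interpolation_mask.astype(np.uint8), 255).astype(np.uint8)
        return sim, Raster(self.grid, mask, nodata=255)


def similarity_one(value: float, training_values) -> float:
    """Similarity of a single value to a training vector (piecewise form)."""
    return float(similarity_vector(np.asarray([value], dtype=float), training_values)[0])


def similarity_vector(values: np.ndarray, training_values) -> np.ndarray:
    """Vectorised per-covariate similarity.

    Degenerate training (all values identical) scores 100 where the
    candidate equals the constant and -100 otherwise: a constant
    environment offers no scale on which to grade departure.
    """
    t = np.sort(np.asarray(training_values, dtype=float))
    if t.size == 0:
        raise ValueError("training vector must be non-empty")
    values = np.asarray(values, dtype=float)
    lo, hi = t[0], t[-1]
    if lo == hi:
        return np.where(values == lo, 100.0, -100.0)
    # f: percentage of training values strictly below each candidate
    f = 100.0 * np.searchsorted(t, values, side="left") / t.size
    span = hi - lo
    out = np.empty_like(values, dtype=float)
    low = f == 0.0
    high = f == 100.0
    mid_lo = (f > 0.0) & (f <= 50.0)
    mid_hi = (f > 50.0) & (f < 100.0)
    out[low] = 100.0 * (values[low] - lo) / span
    out[mid_lo] = 2.0 * f[mid_lo]
    out[mid_hi] = 2.0 * (100.0 - f[mid_hi])
    out[high] = 100.0 * (hi - values[high]) / span
    out[np.isnan(values)] = np.nan
    return out


def extract_training(
    records: list[OccurrenceRecord],
    eor: shapely.Geometry,
    covariates: CovariateStack,
) -> TrainingSample:
    """Training sample from records inside the EOR (boundary inclusive).

    Covariate values are taken from the cell containing each point (no
    interpolation).  Records on nodata cells or outside the grid are
    excluded and logged; fewer than two usable records raises
    :class:`InsufficientTrainingError`.
    """
    grid = covariates.grid
    valid = covariates.valid_mask()
    inside_rc: list[tuple[int, int]] = []
    n_nodata = 0
    for rec in records:
        if not shapely.intersects(eor, shapely.Point(rec.lon, rec.lat)):
            continue
        r, c = grid.cell_of(rec.lon, rec.lat)
        if r < 0 or c < 0 or not valid[r, c]:
            n_nodata += 1
            logger.debug("training record %s on nodata/off-grid cell, excluded", rec)
            continue
        inside_rc.append((r, c))
    if n_nodata:
        logger.info("extract_training: %d within-EOR records on nodata cells excluded", n_nodata)
    if len(inside_rc) < 2:
        raise InsufficientTrainingError(
            f"only {len(inside_rc)} usable within-EOR records; MESS fit refused"
        )
    rows = np.array([rc[0] for rc in inside_rc])
    cols = np.array([rc[1] for rc in inside_rc])
    return TrainingSample({name: arr[rows, cols] for name, arr in covariates.bands.items()})


def mess_surface(
    training: TrainingSample,
    covariates: CovariateStack,
    config: AnalysisConfig | None = None,
) -> MessSurface:
    """Minimum-over-covariates similarity surface on the covariate grid."""
    config = config or AnalysisConfig()
    valid = covariates.valid_mask()
    sim = np.full(covariates.grid.shape, np.inf)
    for name, arr in covariates.bands.items():
        band_sim = similarity_vector(arr.ravel(), training.values[name]).reshape(arr.shape)
        sim = np.minimum(sim, band_sim)
    sim = np.where(valid, sim, np.nan)
    return MessSurface(covariates.grid, sim, threshold=config.mess_positive_threshold)


def classify_records(
    records: list[OccurrenceRecord], surface: MessSurface
) -> list[str]:
    """Label each record by the classification of the cell it falls on."""
    labels = []
    for rec in records:
        r, c = surface.grid.cell_of(rec.lon, rec.lat)
        if r < 0 or c < 0 or not surface.valid[r, c]:
            labels.append(NODATA_LABEL)
        elif surface.interpolation_mask[r, c]:
            labels.append(MESS_POSITIVE)
        else:
            labels.append(MESS_NEGATIVE)
    return labels
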