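"""End-to-end orchestration: registry -> MESS -> ranges -> stacks ->
health metrics -> vulnerability, with output writing and a run manifest.

Stages communicate through in-memory objects; :func:`run_pipeline`
accepts a :class:`~snakevuln.synthetic.Scenario` (or any object exposing
the same layers) and returns a :class:`PipelineResult`.  All layers must
share one grid — a mismatch is a hard error, never a silent resample.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .config import AnalysisConfig
from .grid import GridSpec, Raster, write_ascii_grid
from .health_metrics import assign_haq_deciles, assign_subnational_deciles, classify_travel_time
from .mess import (
    CovariateStack,
    InsufficientTrainingError,
    MESS_POSITIVE,
    classify_records,
    extract_training,
    mess_surface,
)
from .range_builder import EORMap, RangeRaster, buffer_records, build_contemporary_range, rasterize_range, select_outside_records
from .raster_stack import RichnessRaster, composite_layers, no_therapy_layers
from .registry import OccurrenceRecord, SpeciesRecord, assign_groups, dedup_occurrences, join_antivenom, summarize_registry
from .vulnerability import (
    AdminUnit,
    decile_table,
    enumerate_population,
    grand_total,
    population_within_range,
    rasterize_admin_units,
    vulnerability_mask,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "build_species_range", "write_outputs"]


@dataclass
class PipelineResult:
    config: AnalysisConfig
    grid: GridSpec
    registry: list[SpeciesRecord]
    registry_summary: dict
    outside_labels: dict[str, list[str]]
    amended_species: list[str]
    range_rasters: dict[str, RangeRaster]
    range_geometries: dict[str, shapely.Geometry]
    richness: dict[str, RichnessRaster]
    decile_raster: Raster
    decile_thresholds: tuple[float, ...]
    travel_masks: dict[float, np.ndarray]
    vuln_mask_all: np.ndarray
    vuln_mask_no_therapy: np.ndarray
    report_all: pd.DataFrame
    report_no_therapy: pd.DataFrame
    table_all: pd.DataFrame
    table_no_therapy: pd.DataFrame
    summary: dict
    timings: dict[str, float] = field(default_factory=dict)


def build_species_range(
    eor: EORMap,
    records: list[OccurrenceRecord],
    group: str,
    covariates: CovariateStack,
    config: AnalysisConfig,
) -> tuple[shapely.Geometry, int, list[str]]:
    """Contemporary range geometry of one species.

    Group B (or a refused MESS fit) keeps the EOR unchanged.  For group C
    the MESS is fitted on within-EOR records over a window covering the
    EOR and every outside record's buffer disc (padded 10%), outside
    records are classified against it, and MESS-positive ones are
    buffered, masked, and merged.

    Returns (geometry, number of MESS-positive outside records,
    per-outside-record labels).
    """
    if group != "C":
        return eor.geometry, 0, []
    outside = select_outside_records(records, eor)
    pad = config.buffer_radius_deg * 1.1
    ex, ey, ex2, ey2 = shapely.bounds(eor.geometry)
    for r in outside:
        ex, ey = min(ex, r.lon - pad), min(ey, r.lat - pad)
        ex2, ey2 = max(ex2, r.lon + pad), max(ey2, r.lat + pad)
    window = covariates.crop((ex - pad, ey - pad, ex2 + pad, ey2 + pad))
    try:
        training = extract_training(records, eor.geometry, window)
    except InsufficientTrainingError as err:
        logger.warning("%s: %s; EOR retained", eor.species_id, err)
        return eor.geometry, 0, []
    surface = mess_surface(training, window, config)
    labels = classify_records(outside, surface)
    positives = [r for r, lab in zip(outside, labels) if lab == MESS_POSITIVE]
    if not positives:
        return eor.geometry, 0, labels
    buffered = buffer_records(positives, config.buffer_radius_deg, segments=config.buffer_segments)
    geom = build_contemporary_range(eor, buffered, surface)
    return geom, len(positives), labels


def run_pipeline(scenario, config: AnalysisConfig | None = None) -> PipelineResult:
    """Run every stage on an in-memory scenario and collect all outputs."""
    config = config or scenario.config
    grid = scenario.grid
    timings: dict[str, float] = {}

    def tic() -> float:
        return time.perf_counter()

    # -- registry ----------------------------------------------------------
    t0 = tic()
    clean = dedup_occurrences(scenario.occurrences, config)
    by_species: dict[str, list[OccurrenceRecord]] = {}
    for rec in clean:
        by_species.setdefault(rec.species_id, []).append(rec)
    known_ids = {s.species_id for s in scenario.species}
    orphans = set(by_species) - known_ids
    if orphans:
        logger.warning("dropping records for %d species not on the registry: %s",
                       len(orphans), sorted(orphans))
    registry = []
    for s in scenario.species:
        s.n_records = len(by_species.get(s.species_id, []))
        s.has_eor = s.species_id in scenario.eors
        registry.append(s)
    registry = assign_groups(registry, config)
    registry = join_antivenom(registry, scenario.antivenom, default_absent=True)
    registry_summary = summarize_registry(registry)
    logger.info("registry: %s", registry_summary)
    timings["registry"] = tic() - t0

    # -- ranges ------------------------------------------------------------
    t0 = tic()
    range_rasters: dict[str, RangeRaster] = {}
    range_geoms: dict[str, shapely.Geometry] = {}
    outside_labels: dict[str, list[str]] = {}
    amended: list[str] = []
    included = [s for s in registry if s.included]
    for s in included:
        geom, n_pos, labels = build_species_range(
            scenario.eors[s.species_id],
            by_species.get(s.species_id, []),
            s.group,
            scenario.covariates,
            config,
        )
        outside_labels[s.species_id] = labels
        if n_pos > 0:
            amended.append(s.species_id)
        range_geoms[s.species_id] = geom
        range_rasters[s.species_id] = rasterize_range(
            geom, grid, s.species_id, all_touched=config.rasterize_all_touched
        )
    timings["ranges"] = tic() - t0

    # -- richness stacks ---------------------------------------------------
    t0 = tic()
    rasters = [range_rasters[s.species_id] for s in included]
    richness = composite_layers(rasters, included)
    richness.update(no_therapy_layers(rasters, included))
    timings["stack"] = tic() - t0

    # -- health metrics ----------------------------------------------------
    t0 = tic()
    nationals = [u for u in scenario.haq_units if u.level == "national"]
    subnationals = [u for u in scenario.haq_units if u.level == "subnational"]
    nationals, thresholds = assign_haq_deciles(nationals)
    subnationals = assign_subnational_deciles(subnationals, thresholds)
    decile_by_unit = {u.unit_id: u.decile for u in nationals + subnationals}
    admin_units: list[AdminUnit] = []
    for u in scenario.admin_units:
        d = decile_by_unit.get(u.unit_id, decile_by_unit.get(u.country))
        if d is None:
            raise KeyError(f"admin unit {u.unit_id}: no HAQ decile for it or its country")
        admin_units.append(AdminUnit(u.unit_id, u.country, u.geometry, decile=d))
    unit_index = rasterize_admin_units(admin_units, grid)
    decile_values = np.zeros(grid.shape, dtype=np.int16)
    inside = unit_index >= 0
    decile_arr = np.array([u.decile for u in admin_units], dtype=np.int16)
    decile_values[inside] = decile_arr[unit_index[inside]]
    decile_raster = Raster(grid, decile_values, nodata=0)
    scenario.travel.same_grid(grid, names=("travel", "analysis grid"))
    scenario.population.same_grid(grid, names=("population", "analysis grid"))
    travel_masks = {
        t: classify_travel_time(scenario.travel, t) for t in config.travel_thresholds_min
    }
    timings["health"] = tic() - t0

    # -- vulnerability -----------------------------------------------------
    t0 = tic()
    t_max = max(config.travel_thresholds_min)
    mask_all = vulnerability_mask(
        richness["all"], travel_masks[t_max], decile_raster, config.vulnerable_deciles
    )
    mask_nt = vulnerability_mask(
        richness["no_antivenom_all"], travel_masks[t_max], decile_raster, config.vulnerable_deciles
    )
    report_all = enumerate_population(
        mask_all, scenario.population, admin_units,
        unit_index=unit_index, richness=richness["all"], no_therapy_mask=mask_nt,
    )
    report_nt = enumerate_population(
        mask_nt, scenario.population, admin_units,
        unit_index=unit_index, richness=richness["no_antivenom_all"],
    )
    table_all = decile_table(report_all)
    table_nt = decile_table(report_nt)
    summary = {
        "seed": getattr(scenario.spec, "seed", None) if hasattr(scenario, "spec") else None,
        "registry": registry_summary,
        "n_amended_species": len(amended),
        "amended_species": sorted(amended),
        "max_richness": {k: v.max_richness() for k, v in richness.items()},
        "population_in_range_all": population_within_range(
            richness["all"], scenario.population
        ),
        "population_in_range_no_therapy": population_within_range(
            richness["no_antivenom_all"], scenario.population
        ),
        "population_in_range_remote": {
            str(int(t)): population_within_range(
                richness["all"], scenario.population, travel_mask=travel_masks[t]
            )
            for t in config.travel_thresholds_min
        },
        "vulnerable_total_all": grand_total(table_all),
        "vulnerable_total_no_therapy": grand_total(table_nt),
        "assumptions": {
            "delay_mortality_linear_extrapolation": (
                "excess mortality scales linearly at "
                f"{config.mortality_slope_pct_per_hour}%/h beyond the source cohort's range"
            )
        },
    }
    timings["vulnerability"] = tic() - t0

    return PipelineResult(
        config=config,
        grid=grid,
        registry=registry,
        registry_summary=registry_summary,
        outside_labels=outside_labels,
        amended_species=sorted(amended),
        range_rasters=range_rasters,
        range_geometries=range_geoms,
        richness=richness,
        decile_raster=decile_raster,
        decile_thresholds=thresholds.upper,
        travel_masks=travel_masks,
        vuln_mask_all=mask_all,
        vuln_mask_no_therapy=mask_nt,
        report_all=report_all,
        report_no_therapy=report_nt,
        table_all=table_all,
        table_no_therapy=table_nt,
        summary=summary,
        timings=timings,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def write_outputs(result: PipelineResult, outdir: str | Path, *, input_dir: str | Path | None = None) -> Path:
    """Write rasters, report CSVs, summary.json, and the run manifest."""
    outdir = Path(outdir)
    (outdir / "ranges").mkdir(parents=True, exist_ok=True)
    for sid, rr in sorted(result.range_rasters.items()):
        write_ascii_grid(rr.to_raster(), outdir / "ranges" / f"range_{sid}.asc")
    for stratum, rich in result.richness.items():
        write_ascii_grid(rich.to_raster(), outdir / f"richness_{stratum}.asc")
    write_ascii_grid(result.decile_raster, outdir / "haq_decile.asc")
    grid = result.grid
    write_ascii_grid(
        Raster(grid, result.vuln_mask_all.astype(np.uint8), nodata=255),
        outdir / "vulnerability_mask_all.asc",
    )
    write_ascii_grid(
        Raster(grid, result.vuln_mask_no_therapy.astype(np.uint8), nodata=255),
        outdir / "vulnerability_mask_no_therapy.asc",
    )
    # per-stratum maxima and occupied-cell counts
    pd.DataFrame(
        [
            {
                "stratum": k,
                "max_richness": v.max_richness(),
                "occupied_cells": int(((v.counts > 0) & v.valid).sum()),
            }
            for k, v in result.richness.items()
        ]
    ).to_csv(outdir / "richness_summary.csv", index=False)
    pd.DataFrame(
        {"decile": range(1, 11), "haq_upper_value": result.decile_thresholds}
    ).to_csv(outdir / "deciles.csv", index=False)

    for name, report in (
        ("vulnerability_admin2.csv", result.report_all),
        ("vulnerability_admin2_no_therapy.csv", result.report_no_therapy),
    ):
        out = report.copy()
        for col in out.columns:
            if col.startswith("population_"):
                out[col] = out[col].map(_round_half_up)
        out.to_csv(outdir / name, index=False)
    for name, table in (
        ("vulnerability_country_by_decile.csv", result.table_all),
        ("vulnerability_country_by_decile_no_therapy.csv", result.table_no_therapy),
    ):
        table.round(0).astype(np.int64).to_csv(outdir / name, index_label="country")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=float)

    manifest = {
        "software": {"name": "snakevuln", "version": __version__},
        "seed": result.summary.get("seed"),
        "config": result.config.to_dict(),
        "timings_s": {k: round(v, 4) for k, v in result.timings.items()},
        "input_checksums": _checksums(input_dir) if input_dir else {},
        "stages": {k: "ok" for k in result.timings},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _checksums(input_dir: str | Path) -> dict[str, str]:
    out = {}
    for p in sorted(Path(input_dir).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(input_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
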