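"""Synthetic end-to-end scenarios with planted ground truth.

The generator emulates every input the vulnerability analysis consumes —
an environmental covariate stack, expert-opinion ranges (EORs), occurrence
records, gridded population, travel time, HAQ tables, antivenom flags,
and an admin-2 mosaic — at desk scale (default 60 x 60 cells, 12 species,
6 countries), with every planted record carrying its intended MESS label
and every cell its intended stratum membership.

Construction guarantees rather than hopes: covariate bands vary along
longitude only, with one strictly monotone band, so any cell sharing a
longitude column with a training record is certainly environmental
interpolation while any cell beyond the training longitude span is
certainly extrapolation.  Outside records are then *selected from cells
classified by the brute-force MESS oracle* (with a small score margin so
file round-trips cannot flip a label), which makes the planted
interpolation/extrapolation labels exact by construction.  Identical
seeds yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import oracle
from .config import AnalysisConfig
from .grid import GridSpec, Raster, write_ascii_grid, read_ascii_grid
from .health_metrics import HealthUnitRecord
from .io import write_geojson, read_geojson
from .mess import CovariateStack
from .range_builder import EORMap
from .registry import OccurrenceRecord, SpeciesRecord
from .vulnerability import AdminUnit

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "generate_scenario",
    "generate_covariates",
    "expected_vulnerable_population",
    "write_scenario",
    "read_scenario",
]

LABEL_INSIDE = "inside"
LABEL_OUT_INTERP = "outside_interp"
LABEL_OUT_EXTRAP = "outside_extrap"

# selection margin on the extrapolation side: a planted extrapolation cell
# must be negative by a clear margin.  Interpolation cells may score exactly
# zero (a training column revisited is interpolation by the boundary
# convention), which is reproduced bit-exactly across file round-trips.
_SCORE_MARGIN = 1e-6


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario (defaults: desk scale)."""

    seed: int = 0
    nrows: int = 60
    ncols: int = 60
    resolution: float = 0.25
    origin_lon: float = 0.0
    origin_lat: float = 15.0
    n_bands: int = 8
    n_species: int = 12
    n_group_b: int = 2  # species with an EOR but < 5 records (no MESS)
    n_countries: int = 6
    admin2_per_country: int = 3
    n_offstage_countries: int = 14  # HAQ table rows without scene polygons
    n_inside_records: int = 9
    # per group-C species: (n_outside_interp, n_outside_extrap); cycled
    outsider_plan: tuple[tuple[int, int], ...] = (
        (1, 1), (2, 0), (3, 1), (1, 2), (2, 1), (1, 0), (2, 2),  # amendable
        (0, 2), (0, 1), (0, 2),  # extrapolation-only: EOR kept
    )
    nodata_cols: int = 2  # easternmost covariate columns carry no data
    pop_density_range: tuple[int, int] = (5, 50)  # persons per cell
    travel_choices: tuple[float, ...] = (30.0, 120.0, 240.0)
    n_planted_duplicates: int = 3
    n_missing_coord: int = 2

    def grid(self) -> GridSpec:
        return GridSpec(self.origin_lon, self.origin_lat, self.resolution, self.nrows, self.ncols)


@dataclass
class Scenario:
    """A complete generated input set plus its planted ground truth."""

    spec: ScenarioSpec
    config: AnalysisConfig
    grid: GridSpec
    covariates: CovariateStack
    species: list[SpeciesRecord]
    occurrences: list[OccurrenceRecord]
    eors: dict[str, EORMap]
    antivenom: dict[str, bool]
    haq_units: list[HealthUnitRecord]
    admin_units: list[AdminUnit]
    population: Raster
    travel: Raster
    ground_truth: dict = field(default_factory=dict)


def generate_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> CovariateStack:
    """Covariate stack: longitude-varying sinusoid bands plus one strictly
    monotone band; the easternmost ``nodata_cols`` columns carry no data."""
    grid = spec.grid()
    lon, _ = grid.center_coords()
    bands: dict[str, np.ndarray] = {}
    for k in range(spec.n_bands - 1):
        amp = rng.uniform(0.5, 2.5)
        period = rng.uniform(3.0, 9.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        trend = rng.uniform(-0.05, 0.05)
        bands[f"bio{k:02d}"] = amp * np.sin(2 * np.pi * lon / period + phase) + trend * lon
    bands[f"bio{spec.n_bands - 1:02d}"] = lon.copy()  # strictly monotone
    if spec.nodata_cols:
        for arr in bands.values():
            arr[:, -spec.nodata_cols:] = np.nan
    return CovariateStack(grid, bands)


def _eor_cells(spec: ScenarioSpec, rng: np.random.Generator, idx: int) -> tuple[int, int, int, int]:
    """(row0, col0, height, width) of a species EOR in cell units."""
    usable_cols = spec.ncols - spec.nodata_cols - 2
    if idx == 0:
        return 2, 2, 16, 16  # fixed: overlaps the forced low-HAQ remote admin
    h = int(rng.integers(10, 17))
    w = int(rng.integers(10, 17))
    r0 = int(rng.integers(0, spec.nrows - h + 1))
    c0 = int(rng.integers(0, usable_cols - w + 1))
    return r0, c0, h, w


def _three(lo: int, n: int) -> list[int]:
    """Three distinct indices spread over [lo, lo+n): ends and middle."""
    return sorted({lo + 1, lo + n // 2, lo + n - 2})


def generate_scenario(spec: ScenarioSpec | None = None, config: AnalysisConfig | None = None) -> Scenario:
    """Generate the full scenario for one seed; see the module docstring."""
    spec = spec or ScenarioSpec()
    config = config or AnalysisConfig(grid_resolution_deg=spec.resolution)
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    covariates = generate_covariates(spec, rng)
    band_list = [covariates.bands[name] for name in covariates.band_names]
    valid = covariates.valid_mask()

    species: list[SpeciesRecord] = []
    occurrences: list[OccurrenceRecord] = []
    eors: dict[str, EORMap] = {}
    gt_species: dict[str, dict] = {}
    n_group_c = spec.n_species - spec.n_group_b

    for i in range(spec.n_species):
        sid = f"sp{i + 1:02d}"
        group_b = i >= n_group_c
        r0, c0, h, w = _eor_cells(spec, rng, i)
        west, _, _, north = grid.cell_box(r0, c0)
        _, south, east, _ = grid.cell_box(r0 + h - 1, c0 + w - 1)
        eors[sid] = EORMap(sid, box(west, south, east, north))
        year_pool = rng.integers(1990, 2018, size=64)

        # inside records: a 3x3 sub-grid of EOR cells at cell centres, so the
        # training envelope spans the EOR's covariate range in each column
        rows3, cols3 = _three(r0, h), _three(c0, w)
        inside_cells = [(r, c) for r in rows3 for c in cols3]
        if group_b:
            inside_cells = inside_cells[:3]
        recs: list[dict] = []
        for j, (r, c) in enumerate(inside_cells):
            lo, la = grid.cell_center(r, c)
            recs.append({"lon": lo, "lat": la, "year": int(year_pool[j]), "label": LABEL_INSIDE})

        n_interp = n_extrap = 0
        if not group_b:
            n_interp, n_extrap = spec.outsider_plan[i % len(spec.outsider_plan)]
            training = [[float(band[r, c]) for r, c in inside_cells] for band in band_list]
            interp_cells: list[tuple[int, int]] = []
            extrap_cells: list[tuple[int, int]] = []
            for r in range(spec.nrows):
                for c in range(spec.ncols):
                    if not valid[r, c]:
                        continue
                    lo, la = grid.cell_center(r, c)
                    if west <= lo <= east and south <= la <= north:
                        continue  # not outside the EOR
                    score = oracle.min_mess_score([float(b[r, c]) for b in band_list], training)
                    if score >= 0.0:
                        interp_cells.append((r, c))
                    elif score <= -_SCORE_MARGIN:
                        extrap_cells.append((r, c))
            if len(interp_cells) < n_interp or len(extrap_cells) < n_extrap:
                raise RuntimeError(
                    f"{sid}: not enough classified outside cells to plant the plan "
                    f"({len(interp_cells)} interp, {len(extrap_cells)} extrap available)"
                )
            for cells, n, label in (
                (interp_cells, n_interp, LABEL_OUT_INTERP),
                (extrap_cells, n_extrap, LABEL_OUT_EXTRAP),
            ):
                pick = rng.choice(len(cells), size=n, replace=False)
                for j, p in enumerate(sorted(int(x) for x in pick)):
                    r, c = cells[p]
                    lo, la = grid.cell_center(r, c)
                    recs.append(
                        {"lon": lo, "lat": la, "year": int(year_pool[32 + j]), "label": label}
                    )

        for rec in recs:
            occurrences.append(
                OccurrenceRecord(sid, rec["year"], rec["lat"], rec["lon"], source="synthetic")
            )
        species.append(
            SpeciesRecord(
                species_id=sid,
                name=f"Serpens synthetica {i + 1}",
                who_category=1 if i % 2 == 0 else 2,
                has_eor=True,
            )
        )
        gt_species[sid] = {
            "eor_bounds": [west, south, east, north],
            "eor_cells": [r0, c0, h, w],
            "group": "B" if group_b else "C",
            "records": recs,
            "n_records": len(recs),
            "n_inside": len(inside_cells),
            "n_outside_interp": n_interp,
            "n_outside_extrap": n_extrap,
            "amendable": n_interp > 0,
        }

    # noise the pipeline must clean: exact duplicates and missing coordinates
    dup_targets = [occurrences[k] for k in range(spec.n_planted_duplicates)]
    for rec in dup_targets:
        occurrences.append(OccurrenceRecord(rec.species_id, rec.year, rec.lat, rec.lon, "dup"))
    for k in range(spec.n_missing_coord):
        occurrences.append(OccurrenceRecord("sp02", 2000 + k, None, 10.0 + k, "broken"))

    # antivenom flags: random, with sp01 forced therapy-less
    antivenom = {s.species_id: bool(rng.random() < 0.5) for s in species}
    antivenom["sp01"] = False
    antivenom["sp02"] = True

    # countries: vertical strips; admin-2: horizontal substrips of each
    cols_per_country = spec.ncols // spec.n_countries
    rows_per_admin = spec.nrows // spec.admin2_per_country
    admin_units: list[AdminUnit] = []
    admin_cells: dict[str, tuple[int, int, int, int]] = {}
    country_ids = [f"C{i + 1:02d}" for i in range(spec.n_countries)]
    for i, cid in enumerate(country_ids):
        for j in range(spec.admin2_per_country):
            uid = f"{cid}A{j + 1}"
            r0, c0 = j * rows_per_admin, i * cols_per_country
            h = rows_per_admin if j < spec.admin2_per_country - 1 else spec.nrows - r0
            w = cols_per_country if i < spec.n_countries - 1 else spec.ncols - c0
            west, _, _, north = grid.cell_box(r0, c0)
            _, south, east, _ = grid.cell_box(r0 + h - 1, c0 + w - 1)
            admin_units.append(AdminUnit(uid, cid, box(west, south, east, north)))
            admin_cells[uid] = (r0, c0, h, w)

    # HAQ values: scene countries plus offstage rows; C01/C02 forced lowest,
    # C06 forced highest, so deciles 1 and 10 both appear on the map
    haq_values: dict[str, float] = {}
    offstage = [f"X{k + 1:02d}" for k in range(spec.n_offstage_countries)]
    for cid in country_ids + offstage:
        haq_values[cid] = float(np.round(rng.uniform(25.0, 90.0), 1))
    haq_values["C01"] = 18.0
    haq_values["C02"] = 22.0
    haq_values[country_ids[-1]] = 92.0
    haq_units = [
        HealthUnitRecord(cid, v, level="national") for cid, v in sorted(haq_values.items())
    ]
    country_deciles = oracle.national_deciles(haq_values)

    # population and travel time: piecewise constant per admin-2 unit
    pop = np.zeros(grid.shape)
    travel = np.zeros(grid.shape)
    density: dict[str, float] = {}
    minutes: dict[str, float] = {}
    for unit in admin_units:
        r0, c0, h, w = admin_cells[unit.unit_id]
        density[unit.unit_id] = float(
            rng.integers(spec.pop_density_range[0], spec.pop_density_range[1] + 1)
        )
        minutes[unit.unit_id] = float(rng.choice(list(spec.travel_choices)))
    minutes["C01A1"] = 240.0  # forced: remote, lowest-HAQ, within sp01's EOR
    minutes["C01A2"] = 120.0
    minutes[f"{country_ids[-1]}A1"] = 240.0  # remote but high-HAQ: control
    for unit in admin_units:
        r0, c0, h, w = admin_cells[unit.unit_id]
        pop[r0 : r0 + h, c0 : c0 + w] = density[unit.unit_id]
        travel[r0 : r0 + h, c0 : c0 + w] = minutes[unit.unit_id]

    population = Raster(grid, pop, nodata=-9999.0)
    travel_raster = Raster(grid, travel, nodata=-9999.0)

    ground_truth = {
        "seed": spec.seed,
        "species": gt_species,
        "n_amendable": sum(1 for g in gt_species.values() if g["amendable"]),
        "n_occurrences_raw": len(occurrences),
        "n_occurrences_clean": sum(g["n_records"] for g in gt_species.values()),
        "antivenom": antivenom,
        "country_deciles": country_deciles,
        "scene_country_deciles": {c: country_deciles[c] for c in country_ids},
        "per_admin_population": {
            u: density[u] * admin_cells[u][2] * admin_cells[u][3] for u in density
        },
        "per_admin_travel_min": minutes,
        "population_total": float(pop.sum()),
        "travel_gt60_cells": int((travel > 60.0).sum()),
        "travel_gt180_cells": int((travel > 180.0).sum()),
    }
    ground_truth["per_country_population"] = {
        cid: sum(v for u, v in ground_truth["per_admin_population"].items() if u.startswith(cid))
        for cid in country_ids
    }

    scenario = Scenario(
        spec=spec,
        config=config,
        grid=grid,
        covariates=covariates,
        species=species,
        occurrences=occurrences,
        eors=eors,
        antivenom=antivenom,
        haq_units=haq_units,
        admin_units=admin_units,
        population=population,
        travel=travel_raster,
        ground_truth=ground_truth,
    )
    ground_truth["report"] = expected_vulnerable_population(scenario)
    return scenario


def _oracle_presence(scenario: Scenario) -> dict[str, list[list[bool]]]:
    """Per-species presence grids by the brute-force route."""
    spec, grid = scenario.spec, scenario.grid
    band_list = [scenario.covariates.bands[n] for n in scenario.covariates.band_names]
    out: dict[str, list[list[bool]]] = {}
    for sid, gt in scenario.ground_truth["species"].items():
        bounds = tuple(gt["eor_bounds"])
        positives = [
            (r["lon"], r["lat"]) for r in gt["records"] if r["label"] == LABEL_OUT_INTERP
        ]
        if positives:
            inside_cells = [
                grid.cell_of(r["lon"], r["lat"])
                for r in gt["records"]
                if r["label"] == LABEL_INSIDE
            ]
            training = [[float(b[r, c]) for r, c in inside_cells] for b in band_list]
            interp = oracle.interpolation_grid(
                [b.tolist() for b in band_list], training, scenario.config.mess_positive_threshold
            )
        else:
            interp = [[False] * spec.ncols for _ in range(spec.nrows)]
        out[sid] = oracle.expected_presence(
            (grid.origin_lon, grid.origin_lat),
            grid.resolution,
            grid.shape,
            bounds,
            positives,
            interp,
            scenario.config.buffer_radius_deg,
            scenario.config.buffer_segments,
        )
    return out


def expected_vulnerable_population(scenario: Scenario) -> dict:
    """Brute-force vulnerability report for a generated scenario.

    Recomputes species presence, strata, and population sums by explicit
    per-cell loops (:mod:`snakevuln.oracle`), sharing no code with the
    pipeline modules under test.
    """
    spec = scenario.spec
    presence = _oracle_presence(scenario)
    admin_of_cell: list[list[str | None]] = [
        [None] * spec.ncols for _ in range(spec.nrows)
    ]
    cols_per_country = spec.ncols // spec.n_countries
    rows_per_admin = spec.nrows // spec.admin2_per_country
    for r in range(spec.nrows):
        j = min(r // rows_per_admin, spec.admin2_per_country - 1)
        for c in range(spec.ncols):
            i = min(c // cols_per_country, spec.n_countries - 1)
            admin_of_cell[r][c] = f"C{i + 1:02d}A{j + 1}"
    report = oracle.expected_report(
        scenario.grid.shape,
        presence,
        {sid for sid, av in scenario.antivenom.items() if not av},
        admin_of_cell,
        {u.unit_id: u.country for u in scenario.admin_units},
        scenario.ground_truth["scene_country_deciles"],
        scenario.travel.values.tolist(),
        scenario.population.values.tolist(),
        travel_threshold=max(scenario.config.travel_thresholds_min),
        vulnerable_deciles=set(scenario.config.vulnerable_deciles),
    )
    return report


# ---------------------------------------------------------------------------
# scenario directory round-trip


def write_scenario(scenario: Scenario, outdir: str | Path) -> Path:
    """Write the complete input directory (CSV/asc/GeoJSON) + ground truth."""
    outdir = Path(outdir)
    (outdir / "covariates").mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "name": s.name,
                "who_category": s.who_category,
                "has_eor": s.has_eor,
            }
            for s in scenario.species
        ]
    ).to_csv(outdir / "registry.csv", index=False)
    pd.DataFrame(
        [
            {"species_id": r.species_id, "year": r.year, "lat": r.lat, "lon": r.lon, "source": r.source}
            for r in scenario.occurrences
        ]
    ).to_csv(outdir / "occurrences.csv", index=False)
    pd.DataFrame(
        [{"species_id": k, "antivenom_available": v} for k, v in sorted(scenario.antivenom.items())]
    ).to_csv(outdir / "antivenom.csv", index=False)
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "parent_country": u.parent_country or "",
                "level": u.level,
                "haq_value": u.haq_value,
            }
            for u in scenario.haq_units
        ]
    ).to_csv(outdir / "haq.csv", index=False)
    manifest = []
    for name in scenario.covariates.band_names:
        fname = f"{name}.asc"
        write_ascii_grid(
            Raster(scenario.grid, np.nan_to_num(scenario.covariates.bands[name], nan=-9999.0),
                   nodata=-9999.0),
            outdir / "covariates" / fname,
        )
        manifest.append({"band": name, "file": f"covariates/{fname}"})
    pd.DataFrame(manifest).to_csv(outdir / "covariates" / "manifest.csv", index=False)
    write_ascii_grid(scenario.population, outdir / "population.asc")
    write_ascii_grid(scenario.travel, outdir / "travel_time.asc")
    write_geojson(
        [(e.geometry, {"species_id": sid}) for sid, e in sorted(scenario.eors.items())],
        outdir / "eor.geojson",
    )
    write_geojson(
        [(u.geometry, {"unit_id": u.unit_id, "country": u.country}) for u in scenario.admin_units],
        outdir / "admin2.geojson",
    )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(scenario.ground_truth, fh, indent=1, sort_keys=True)
    scenario.config.to_yaml(outdir / "config.yaml")
    return outdir


def read_scenario(indir: str | Path) -> Scenario:
    """Reload a scenario directory written by :func:`write_scenario`."""
    from .registry import read_occurrences_csv, read_registry_csv
    from .io import read_antivenom_csv, read_haq_csv

    indir = Path(indir)
    config = AnalysisConfig.from_yaml(indir / "config.yaml")
    manifest = pd.read_csv(indir / "covariates" / "manifest.csv")
    bands: dict[str, np.ndarray] = {}
    grid = None
    for row in manifest.itertuples(index=False):
        rast = read_ascii_grid(indir / str(row.file))
        grid = grid or rast.grid
        if rast.grid != grid:
            raise ValueError(f"covariate band {row.band} is on a different grid")
        vals = rast.values.astype(float)
        vals[vals == rast.nodata] = np.nan
        bands[str(row.band)] = vals
    covariates = CovariateStack(grid, bands)
    species = read_registry_csv(indir / "registry.csv")
    occurrences = read_occurrences_csv(indir / "occurrences.csv")
    antivenom = read_antivenom_csv(indir / "antivenom.csv")
    haq_units = read_haq_csv(indir / "haq.csv")
    eors = {
        str(props["species_id"]): EORMap(str(props["species_id"]), geom)
        for geom, props in read_geojson(indir / "eor.geojson")
    }
    admin_units = [
        AdminUnit(str(p["unit_id"]), str(p["country"]), geom)
        for geom, p in read_geojson(indir / "admin2.geojson")
    ]
    population = read_ascii_grid(indir / "population.asc")
    travel = read_ascii_grid(indir / "travel_time.asc")
    gt_path = indir / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    spec = ScenarioSpec(
        seed=int(ground_truth.get("seed", -1)),
        nrows=grid.nrows,
        ncols=grid.ncols,
        resolution=grid.resolution,
        origin_lon=grid.origin_lon,
        origin_lat=grid.origin_lat,
        n_bands=len(bands),
        n_species=len(species),
    )
    return Scenario(
        spec=spec,
        config=config,
        grid=grid,
        covariates=covariates,
        species=species,
        occurrences=occurrences,
        eors=eors,
        antivenom=antivenom,
        haq_units=haq_units,
        admin_units=admin_units,
        population=population,
        travel=travel,
        ground_truth=ground_truth,
    )
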