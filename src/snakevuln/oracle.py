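"""Brute-force reference computations for synthetic scenarios.

Everything here is deliberately naive — explicit per-cell and per-record
Python loops, scalar arithmetic, no code shared with the pipeline modules
— so that agreement between a pipeline output and its oracle counterpart
is evidence, not tautology.  The only shared dependency is shapely's
point-in-polygon primitive (and the same 64-segment disc approximation
the range builder documents, so boolean layers can agree exactly).

Inputs are plain arrays and dicts describing the scenario; see
:mod:`snakevuln.synthetic` for the generator that prepares them.
"""

from __future__ import annotations

import math

from shapely.geometry import Point

__all__ = [
    "mess_score",
    "min_mess_score",
    "expected_presence",
    "expected_report",
]


def mess_score(value: float, training: list[float]) -> float:
    """Piecewise similarity of one value to a training vector (scalar)."""
    lo, hi = min(training), max(training)
    if lo == hi:
        return 100.0 if value == lo else -100.0
    below = sum(1 for t in training if t < value)
    f = 100.0 * below / len(training)
    if f == 0.0:
        return 100.0 * (value - lo) / (hi - lo)
    if f <= 50.0:
        return 2.0 * f
    if f < 100.0:
        return 2.0 * (100.0 - f)
    return 100.0 * (hi - value) / (hi - lo)


def min_mess_score(cell_values: list[float], training_per_band: list[list[float]]) -> float:
    """Minimum across covariates of the per-band score."""
    return min(
        mess_score(v, t) for v, t in zip(cell_values, training_per_band)
    )


def _cell_values(bands: list, r: int, c: int) -> list[float] | None:
    """Per-band values at one cell; None when any band is nodata (NaN)."""
    vals = []
    for band in bands:
        v = float(band[r][c])
        if math.isnan(v):
            return None
        vals.append(v)
    return vals


def interpolation_grid(
    bands: list, training_per_band: list[list[float]], threshold: float = 0.0
) -> list[list[bool]]:
    """Per-cell MESS-positive classification by direct formula evaluation."""
    nrows, ncols = len(bands[0]), len(bands[0][0])
    out = []
    for r in range(nrows):
        row = []
        for c in range(ncols):
            vals = _cell_values(bands, r, c)
            row.append(vals is not None and min_mess_score(vals, training_per_band) >= threshold)
        out.append(row)
    return out


def expected_presence(
    grid_origin: tuple[float, float],
    resolution: float,
    shape: tuple[int, int],
    eor_bounds: tuple[float, float, float, float],
    positive_records: list[tuple[float, float]],
    interp: list[list[bool]],
    buffer_radius: float,
    buffer_segments: int = 64,
) -> list[list[bool]]:
    """Per-cell presence of one species, from first principles.

    A cell is present iff its centre lies in the EOR rectangle (edges
    inclusive), or lies within the polygonal buffer disc of a valid
    (MESS-positive) outside record while the cell itself is environmental
    interpolation.
    """
    olon, olat = grid_origin
    nrows, ncols = shape
    minx, miny, maxx, maxy = eor_bounds
    discs = [
        Point(x, y).buffer(buffer_radius, quad_segs=buffer_segments // 4)
        for x, y in positive_records
    ]
    out = []
    for r in range(nrows):
        row = []
        lat = olat - (r + 0.5) * resolution
        for c in range(ncols):
            lon = olon + (c + 0.5) * resolution
            present = minx <= lon <= maxx and miny <= lat <= maxy
            if not present and interp[r][c]:
                pt = Point(lon, lat)
                present = any(d.intersects(pt) for d in discs)
            row.append(present)
        out.append(row)
    return out


def expected_report(
    shape: tuple[int, int],
    presence_by_species: dict[str, list[list[bool]]],
    no_therapy_species: set[str],
    admin_of_cell: list[list[str | None]],
    country_of_admin: dict[str, str],
    decile_of_country: dict[str, int],
    travel_minutes: list[list[float]],
    population: list[list[float]],
    travel_threshold: float,
    vulnerable_deciles: set[int],
) -> dict:
    """Vulnerability enumeration by explicit per-cell looping.

    Returns per-admin, per-country, and per-decile vulnerable-population
    sums for both strata (any species / no-therapy species only), the
    in-range population totals, and the grand totals.
    """
    nrows, ncols = shape
    per_admin_all: dict[str, float] = {}
    per_admin_nt: dict[str, float] = {}
    per_country_all: dict[str, float] = {}
    per_country_nt: dict[str, float] = {}
    per_decile_all: dict[int, float] = {}
    per_decile_nt: dict[int, float] = {}
    in_range_all = in_range_nt = 0.0
    total_all = total_nt = 0.0
    richness_max = 0
    for r in range(nrows):
        for c in range(ncols):
            n_any = sum(1 for p in presence_by_species.values() if p[r][c])
            n_nt = sum(
                1 for sid, p in presence_by_species.items() if p[r][c] and sid in no_therapy_species
            )
            richness_max = max(richness_max, n_any)
            pop = population[r][c]
            if n_any:
                in_range_all += pop
            if n_nt:
                in_range_nt += pop
            admin = admin_of_cell[r][c]
            if admin is None:
                continue
            country = country_of_admin[admin]
            decile = decile_of_country[country]
            remote = travel_minutes[r][c] > travel_threshold
            if not (remote and decile in vulnerable_deciles):
                continue
            if n_any:
                per_admin_all[admin] = per_admin_all.get(admin, 0.0) + pop
                per_country_all[country] = per_country_all.get(country, 0.0) + pop
                per_decile_all[decile] = per_decile_all.get(decile, 0.0) + pop
                total_all += pop
            if n_nt:
                per_admin_nt[admin] = per_admin_nt.get(admin, 0.0) + pop
                per_country_nt[country] = per_country_nt.get(country, 0.0) + pop
                per_decile_nt[decile] = per_decile_nt.get(decile, 0.0) + pop
                total_nt += pop
    return {
        "per_admin_all": per_admin_all,
        "per_admin_no_therapy": per_admin_nt,
        "per_country_all": per_country_all,
        "per_country_no_therapy": per_country_nt,
        "per_decile_all": {int(k): v for k, v in per_decile_all.items()},
        "per_decile_no_therapy": {int(k): v for k, v in per_decile_nt.items()},
        "grand_total_all": total_all,
        "grand_total_no_therapy": total_nt,
        "population_in_range_all": in_range_all,
        "population_in_range_no_therapy": in_range_nt,
        "max_richness": richness_max,
    }


def decile_of_rank(rank: int, n: int) -> int:
    """Decile of the unit at ascending 0-based rank among n units."""
    return (10 * rank) // n + 1


def national_deciles(values_by_country: dict[str, float]) -> dict[str, int]:
    """Sort-based decile assignment (ties broken by country id)."""
    ranked = sorted(values_by_country.items(), key=lambda kv: (kv[1], kv[0]))
    return {cid: decile_of_rank(i, len(ranked)) for i, (cid, _) in enumerate(ranked)}
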