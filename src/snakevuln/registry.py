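"""Species registry and occurrence-record handling.

The analysis starts from the WHO list of medically important venomous
snakes (category 1: common, high-impact species; category 2: species of
lesser or less documented clinical impact) and georeferenced occurrence
records assembled from public biodiversity databases.  This module cleans
the records (duplicate and missing-coordinate removal), assigns each
species a data-availability group, and joins the WHO antivenom-availability
flag:

* group A — no expert-opinion range (EOR) map and no records: excluded;
* group B — EOR map but fewer than ``min_records_group_c`` records;
* group C — EOR map and at least that many records (MESS-eligible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "OccurrenceRecord",
    "SpeciesRecord",
    "dedup_occurrences",
    "assign_group",
    "summarize_registry",
    "join_antivenom",
    "read_occurrences_csv",
    "read_registry_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced sighting of a species."""

    species_id: str
    year: int | None
    lat: float | None
    lon: float | None
    source: str = ""

    @property
    def has_coords(self) -> bool:
        return self.lat is not None and self.lon is not None


@dataclass
class SpeciesRecord:
    """One registry row: WHO category, availability group, antivenom flag."""

    species_id: str
    name: str
    who_category: int
    has_eor: bool
    n_records: int = 0
    group: str | None = None
    antivenom_available: bool | None = None

    def __post_init__(self) -> None:
        if self.who_category not in (1, 2):
            raise ValueError(
                f"{self.species_id}: who_category must be 1 or 2, got {self.who_category}"
            )
        if self.n_records < 0:
            raise ValueError(f"{self.species_id}: n_records must be nonnegative")

    @property
    def included(self) -> bool:
        return self.group in ("B", "C")


def _coord_valid(lat, lon) -> bool:
    return lat is not None and lon is not None and -90 <= lat <= 90 and -180 <= lon <= 180


def dedup_occurrences(
    records: Iterable[OccurrenceRecord], config: AnalysisConfig | None = None
) -> list[OccurrenceRecord]:
    """Remove duplicate and coordinate-missing occurrence records.

    Two records of the same species are duplicates when their
    (collection year, latitude, longitude) tuples coincide, coordinates
    compared after rounding to ``config.coord_decimals`` places.  Records
    missing either coordinate (or with a coordinate outside the valid
    WGS84 range) are dropped.  Records missing the collection year are
    kept and collapse only with other missing-year records at the same
    rounded coordinates.  First occurrence order is preserved, which
    makes the operation idempotent.
    """
    config = config or AnalysisConfig()
    nd = config.coord_decimals
    seen: set[tuple] = set()
    kept: list[OccurrenceRecord] = []
    n_dup = n_missing = 0
    for rec in records:
        if not _coord_valid(rec.lat, rec.lon):
            n_missing += 1
            logger.debug("dropping %s: missing or invalid coordinates", rec)
            continue
        key = (rec.species_id, rec.year, round(rec.lat, nd), round(rec.lon, nd))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(rec)
    if n_dup or n_missing:
        logger.info(
            "dedup_occurrences: kept %d, removed %d duplicates and %d missing/invalid-coordinate records",
            len(kept), n_dup, n_missing,
        )
    return kept


def assign_group(has_eor: bool, n_records: int, config: AnalysisConfig | None = None) -> str:
    """Data-availability group of one species.

    Species with records but no EOR map cannot be mapped (there is no
    range to refine) and are folded into the excluded group A; this is
    logged prominently since it silently removes observed species.
    """
    if n_records < 0:
        raise ValueError("n_records must be nonnegative")
    config = config or AnalysisConfig()
    if not has_eor:
        if n_records > 0:
            logger.warning(
                "species with %d occurrence records but no EOR map: unmappable, excluded as group A",
                n_records,
            )
        return "A"
    return "C" if n_records >= config.min_records_group_c else "B"


def assign_groups(
    species: Iterable[SpeciesRecord], config: AnalysisConfig | None = None
) -> list[SpeciesRecord]:
    """Assign the availability group to every registry row (post-dedup counts)."""
    return [replace(s, group=assign_group(s.has_eor, s.n_records, config)) for s in species]


def summarize_registry(species: Iterable[SpeciesRecord]) -> dict:
    """Tally the registry by group, WHO category, and antivenom status."""
    species = list(species)
    by_group = {g: sum(1 for s in species if s.group == g) for g in ("A", "B", "C")}
    included = [s for s in species if s.included]
    by_category = {c: sum(1 for s in included if s.who_category == c) for c in (1, 2)}
    n_av = sum(1 for s in included if s.antivenom_available is True)
    n_no = sum(1 for s in included if s.antivenom_available is False)
    return {
        "n_total": len(species),
        "by_group": by_group,
        "n_included": len(included),
        "included_by_category": by_category,
        "n_antivenom_available": n_av,
        "n_no_antivenom": n_no,
        "no_antivenom_by_category": {
            c: sum(1 for s in included if s.antivenom_available is False and s.who_category == c)
            for c in (1, 2)
        },
    }


def join_antivenom(
    species: Iterable[SpeciesRecord],
    antivenom_table: Mapping[str, bool],
    *,
    default_absent: bool = True,
) -> list[SpeciesRecord]:
    """Attach the WHO antivenom-availability flag to every species.

    Species absent from the table default to unavailable when
    ``default_absent`` (a species with no listing has no documented
    therapy); otherwise a missing entry is an error.
    """
    out = []
    for s in species:
        if s.species_id in antivenom_table:
            avail = bool(antivenom_table[s.species_id])
        elif default_absent:
            avail = False
        else:
            raise KeyError(f"species {s.species_id} missing from the antivenom table")
        out.append(replace(s, antivenom_available=avail))
    return out


def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read occurrence records (columns species_id,year,lat,lon,source).

    Non-numeric coordinates and years are treated as missing rather than
    raising, so a single malformed row cannot abort ingestion.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "source": str})
    required = {"species_id", "year", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        year = pd.to_numeric(getattr(row, "year"), errors="coerce")
        lat = pd.to_numeric(getattr(row, "lat"), errors="coerce")
        lon = pd.to_numeric(getattr(row, "lon"), errors="coerce")
        records.append(
            OccurrenceRecord(
                species_id=str(row.species_id),
                year=None if pd.isna(year) else int(year),
                lat=None if pd.isna(lat) else float(lat),
                lon=None if pd.isna(lon) else float(lon),
                source=str(getattr(row, "source", "") or ""),
            )
        )
    return records


def read_registry_csv(path: str | Path) -> list[SpeciesRecord]:
    """Read the species registry (columns species_id,name,who_category,has_eor[,antivenom_available])."""
    df = pd.read_csv(path, dtype={"species_id": str, "name": str})
    out = []
    for row in df.itertuples(index=False):
        av = getattr(row, "antivenom_available", None)
        out.append(
            SpeciesRecord(
                species_id=str(row.species_id),
                name=str(row.name),
                who_category=int(row.who_category),
                has_eor=bool(row.has_eor),
                antivenom_available=None if av is None or pd.isna(av) else bool(av),
            )
        )
    return out
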