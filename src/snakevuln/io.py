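"""GeoJSON vector I/O and small table readers shared by the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

__all__ = ["write_geojson", "read_geojson", "read_antivenom_csv", "read_haq_csv"]


def write_geojson(features: list[tuple[shapely.Geometry, dict]], path: str | Path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path: str | Path) -> list[tuple[shapely.Geometry, dict]]:
    """Read a GeoJSON FeatureCollection into (geometry, properties) pairs."""
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        (shape(feat["geometry"]), feat.get("properties") or {})
        for feat in fc.get("features", [])
    ]


def read_antivenom_csv(path: str | Path) -> dict[str, bool]:
    """Columns species_id,antivenom_available -> mapping."""
    df = pd.read_csv(path, dtype={"species_id": str})
    return {
        str(r.species_id): bool(r.antivenom_available) for r in df.itertuples(index=False)
    }


def read_haq_csv(path: str | Path):
    """Columns unit_id,parent_country,level,haq_value -> HealthUnitRecords."""
    from .health_metrics import HealthUnitRecord

    df = pd.read_csv(path, dtype={"unit_id": str})
    units = []
    for r in df.itertuples(index=False):
        parent = getattr(r, "parent_country", None)
        units.append(
            HealthUnitRecord(
                unit_id=str(r.unit_id),
                haq_value=float(r.haq_value),
                level=str(getattr(r, "level", "national")),
                parent_country=None if parent is None or pd.isna(parent) else str(parent),
            )
        )
    return units
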