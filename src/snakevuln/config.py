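"""Analysis configuration: every tunable constant of the pipeline.

Defaults reproduce the published study conditions: group-C membership at
>=5 occurrence records, a 0.898 degree record buffer (about 100 km at the
equator), travel-time remoteness thresholds of 1 h and 3 h, HAQ deciles 1-3
as the low-quality stratum, a 1.01 percentage-point mortality increase per
hour of treatment delay, and a MESS interpolation threshold of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

__all__ = ["AnalysisConfig", "KM_PER_DEGREE_EQUATOR"]

# Equatorial arc length of one degree of longitude (WGS84 equatorial
# radius 6378.137 km): 2*pi*6378.137/360.
KM_PER_DEGREE_EQUATOR = 111.31949079327357


@dataclass
class AnalysisConfig:
    min_records_group_c: int = 5
    buffer_radius_deg: float = 0.898
    travel_thresholds_min: tuple[float, ...] = (60.0, 180.0)
    vulnerable_deciles: frozenset[int] = frozenset({1, 2, 3})
    mortality_slope_pct_per_hour: float = 1.01
    grid_resolution_deg: float = 0.0416667  # ~5 km at the equator
    mess_positive_threshold: float = 0.0
    coord_decimals: int = 6  # coordinate rounding for duplicate detection
    buffer_segments: int = 64  # polygonal approximation of buffer discs
    rasterize_all_touched: bool = False

    def __post_init__(self) -> None:
        self.vulnerable_deciles = frozenset(int(d) for d in self.vulnerable_deciles)
        if self.min_records_group_c <= 0:
            raise ValueError("min_records_group_c must be positive")
        if self.buffer_radius_deg <= 0:
            raise ValueError("buffer_radius_deg must be positive")
        if any(t <= 0 for t in self.travel_thresholds_min):
            raise ValueError("travel thresholds must be positive")
        if not self.vulnerable_deciles <= set(range(1, 11)):
            raise ValueError("vulnerable_deciles must be a subset of 1..10")
        if self.grid_resolution_deg <= 0:
            raise ValueError("grid_resolution_deg must be positive")

    @property
    def buffer_radius_km_equator(self) -> float:
        """The buffer radius expressed as an equatorial arc, in km."""
        return self.buffer_radius_deg * KM_PER_DEGREE_EQUATOR

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vulnerable_deciles"] = sorted(self.vulnerable_deciles)
        d["travel_thresholds_min"] = list(self.travel_thresholds_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "vulnerable_deciles" in d:
            d["vulnerable_deciles"] = frozenset(d["vulnerable_deciles"])
        if "travel_thresholds_min" in d:
            d["travel_thresholds_min"] = tuple(d["travel_thresholds_min"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("analysis", data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"analysis": self.to_dict()}, fh, sort_keys=True)
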