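"""Study configuration: one human-editable file driving every stage.

``StudyConfig`` collects the synthetic-city parameters and every
analysis default (hexagon side, time thresholds, mode speeds and detour
factors, detection windows, grading and deviation-band parameters) and
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from greenaccess.accessibility import DEFAULT_SPEEDS, MODES
from greenaccess.synthetic import CityConfig

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """All tunables of the end-to-end analysis."""

    city: CityConfig = field(default_factory=CityConfig)
    thresholds_min: tuple[float, ...] = (15.0, 30.0)
    speeds_kmh: dict = field(default_factory=lambda: dict(DEFAULT_SPEEDS))
    detour_factors: dict = field(default_factory=lambda: {"walking": 1.3, "cycling": 1.3, "driving": 1.4})
    min_residence_days: int = 10
    night_start_h: float = 21.0
    night_end_h: float = 8.0
    day_start_h: float = 8.0
    day_end_h: float = 21.0
    min_visit_dwell_min: float = 30.0
    large_area_threshold_hm2: float = 100.0
    grade_classes: int = 5
    grade_ratio: float = 2.0
    z_low: float = 0.8
    z_high: float = 1.2
    level_source: str = "grade"   # "grade" (1–5 accessibility level) or "comprehensive" (raw C_i)

    def __post_init__(self) -> None:
        if isinstance(self.city, dict):
            self.city = CityConfig(**self.city)
        for mode in MODES:
            if mode not in self.speeds_kmh:
                raise ValueError(f"missing speed for mode {mode!r}")
            if self.speeds_kmh[mode] <= 0:
                raise ValueError(f"speed for {mode} must be positive")
            if self.detour_factors.get(mode, 1.0) < 1.0:
                raise ValueError(f"detour factor for {mode} must be at least 1")
        if any(t <= 0 for t in self.thresholds_min):
            raise ValueError("time thresholds must be positive")
        if self.level_source not in ("grade", "comprehensive"):
            raise ValueError("level_source must be 'grade' or 'comprehensive'")
        if not 0 < self.z_low <= self.z_high:
            raise ValueError("deviation bands must satisfy 0 < low <= high")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["city"]["extent"] = list(self.city.extent)
        d["city"]["entrances_per_large_park"] = list(self.city.entrances_per_large_park)
        d["city"]["target_mode_shares"] = list(self.city.target_mode_shares)
        d["city"]["pop_centers"] = [list(c) for c in self.city.pop_centers]
        d["thresholds_min"] = list(self.thresholds_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        city = dict(d.pop("city", {}))
        for key in ("extent", "entrances_per_large_park", "target_mode_shares"):
            if key in city:
                city[key] = tuple(city[key])
        if "pop_centers" in city:
            city["pop_centers"] = [tuple(c) for c in city["pop_centers"]]
        if "thresholds_min" in d:
            d["thresholds_min"] = tuple(d["thresholds_min"])
        return cls(city=CityConfig(**city), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the full configuration (used in the run manifest)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
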