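"""Analysis configuration with YAML round-trip.

Collects every tunable constant of the pipeline in one dataclass: the radius
grid (1..240 nm at 1 nm), envelope simulation count and levels (99%
univariate, 95% bivariate), LBI integration bounds (10-110 nm), the 15 nm
oligomer linkage distance, bootstrap count, seed, and the pixel->nm scale for
ImageJ measurement exports.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .patterns import StudyRegion, ValidationError, radius_grid

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    r_min: float = 1.0
    r_max: float = 240.0
    r_step: float = 1.0
    n_envelope: int = 1000
    univariate_level: float = 0.99
    bivariate_level: float = 0.95
    envelope_floor: float = 1e-6
    lbi_bounds: tuple[float, float] = (10.0, 110.0)
    linkage_nm: float = 15.0
    oligomer_min_size: int = 3
    n_bootstrap: int = 1000
    seed: int = 0
    pixel_size_nm: float | None = None
    column_map: dict[str, str] | None = None
    unbiased_k: bool = False
    weighting: str = "points"
    shift_channel: str = "small"
    region_width: float = 1000.0
    region_height: float = 1000.0

    def __post_init__(self) -> None:
        self.lbi_bounds = (float(self.lbi_bounds[0]), float(self.lbi_bounds[1]))
        if self.n_envelope < 1 or self.n_bootstrap < 1:
            raise ValidationError("simulation counts must be >= 1")
        for lv in (self.univariate_level, self.bivariate_level):
            if not (0.0 < lv < 1.0):
                raise ValidationError(f"confidence level must be in (0, 1), got {lv}")
        self.radii  # validates the grid bounds/step
        lo, hi = self.lbi_bounds
        if lo >= hi:
            raise ValidationError(f"LBI bounds {self.lbi_bounds} must be increasing")
        # containment of the LBI bounds in the grid is enforced where the
        # integral is taken, so univariate-only configs may use short grids
        if self.linkage_nm <= 0:
            raise ValidationError("linkage_nm must be > 0")
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be > 0")
        if self.weighting not in ("points", "equal"):
            raise ValidationError("weighting must be 'points' or 'equal'")
        if self.shift_channel not in ("big", "small"):
            raise ValidationError("shift_channel must be 'big' or 'small'")

    @property
    def radii(self) -> np.ndarray:
        return radius_grid(self.r_min, self.r_max, self.r_step)

    @property
    def region(self) -> StudyRegion:
        return StudyRegion(self.region_width, self.region_height)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lbi_bounds"] = list(self.lbi_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        region = d.pop("region", None)
        if isinstance(region, dict):
            d.setdefault("region_width", region.get("width", 1000.0))
            d.setdefault("region_height", region.get("height", 1000.0))
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "lbi_bounds" in d and d["lbi_bounds"] is not None:
            d["lbi_bounds"] = tuple(d["lbi_bounds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
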