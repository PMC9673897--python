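"""Pipeline configuration: the method's constants plus input/output paths.

The defaults reproduce the published parameters: 3 km component buffer,
urban settlement classes 21–30, 100,000 m² fringe threshold, 1 ha minimum
unit area, 30-unit extent minimum, quality flag 1, apothems 3–11 m in 1 m
steps, and −99 as the no-data value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    buffer_m: float = 3000.0
    smod_urban_min: int = 21
    smod_urban_max: int = 30
    fringe_area_m2: float = 100_000.0
    min_unit_area_m2: float = 10_000.0
    min_units_per_extent: int = 30
    apothem_min_m: float = 3.0
    apothem_max_m: float = 11.0
    apothem_step_m: float = 1.0
    nodata: int = -99
    qa_required: int = 1
    iso3: str = "XXX"
    adm0_name: str = ""
    seed: int = 0  # synthetic generation only
    keep_intermediates: bool = False

    # input paths (all optional so in-memory runs need no files)
    smod_path: Optional[str] = None
    centres_path: Optional[str] = None
    admin_path: Optional[str] = None
    water_path: Optional[str] = None
    lines_path: Optional[str] = None
    landuse_path: Optional[str] = None
    residential_path: Optional[str] = None
    settlements_path: Optional[str] = None
    footprints_path: Optional[str] = None
    population_path: Optional[str] = None
    surface_area_path: Optional[str] = None
    out_dir: str = "output"

    def __post_init__(self) -> None:
        for name in ("buffer_m", "fringe_area_m2", "min_unit_area_m2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.min_units_per_extent < 1:
            raise ConfigError("min_units_per_extent must be positive")
        if not (self.apothem_min_m >= 1 and self.apothem_max_m >= self.apothem_min_m):
            raise ConfigError("invalid apothem range")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML (or JSON) key-value config file, with overrides."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
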