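"""Structured run configuration: YAML files validated by pydantic.

Unknown keys are rejected everywhere; a config either round-trips
losslessly through save/load or fails with an error naming the field
and section.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .fabrication import MachineProfile, ShrinkageModel
from .vo_pipeline import HiveSpec, OffsetSchedule


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpecConfig(_Strict):
    cavity_target_volume: float = Field(gt=0, description="litres")
    cavity_height: float = Field(gt=0, description="cm")
    entrance_diameter: float = Field(gt=0, description="mm")
    channel_diameter: float = Field(default=25.0, gt=0, description="mm")
    roof_thickness: float = Field(default=60.0, gt=0, description="mm")
    landing_platform: Optional[tuple[float, float]] = (120.0, 80.0)
    design_load: float = Field(default=80.0, ge=0, description="kgf")
    occupancy: int = Field(default=60_000, gt=0)

    def build(self) -> HiveSpec:
        return HiveSpec(**self.model_dump())


class ScheduleEntryConfig(_Strict):
    distance: float = Field(gt=0, description="zone width, mm")
    role: Literal["wall", "weave", "channel"]


class MachineConfig(_Strict):
    max_print_diameter: float = Field(default=40.0, gt=0, description="cm")
    max_module_height: float = Field(default=15.0, gt=0, description="cm")
    bead_width: float = Field(default=3.0, gt=0, description="mm")
    layer_height: float = Field(default=2.0, gt=0, description="mm")
    filament_diameter: Optional[float] = Field(
        default=None, description="mm; omit for paste extruders")
    feed_rate: float = Field(default=30.0, gt=0, description="mm/s")

    def build(self) -> MachineProfile:
        return MachineProfile(**self.model_dump())


class VOConfig(_Strict):
    cell_size: float = Field(default=8.0, gt=0, description="weave cell circumradius, mm")
    roof_layers: Optional[int] = None
    roof_weave_scale: float = 1.5
    shape: Literal["cylinder", "tapered"] = "cylinder"
    taper_ratio: float = 1.0
    cavity_segments: int = 128


class ISConfig(_Strict):
    dims: tuple[int, int, int] = (16, 16, 12)
    iterations: int = Field(default=15, ge=1)
    variant: Literal["enclosed", "open"] = "enclosed"
    volume_fraction: float = Field(default=0.45, gt=0, le=1)
    penalization: float = 3.0
    filter_radius: float = 1.5
    threshold: float = Field(default=0.5, gt=0, lt=1)
    feed_mode: Literal["infill", "self"] = "infill"


class ExploreConfig(_Strict):
    population: int = 24
    clusters: int = 4
    generations: int = 10
    target_volume: float = 30.0
    weights: Optional[dict[str, float]] = None


class FabricationConfig(_Strict):
    shrinkage: float = Field(default=0.0, ge=0, lt=0.5,
                             description="linear shrink factor per axis")
    material_density: float = Field(default=1.3, gt=0, description="g/cm^3")

    def shrinkage_model(self) -> ShrinkageModel:
        return ShrinkageModel.isotropic(self.shrinkage)


class ValidationConfig(_Strict):
    cavity_volume_l: tuple[float, float] = (25.0, 40.0)
    entrance_diameter_mm: Optional[tuple[float, float]] = None
    design_load_kgf: float = 80.0


class RunConfig(_Strict):
    pipeline: Literal["vo", "is", "explore", "slice", "gcode", "validate"]
    seed: int = 0
    out_dir: str = "out"
    note: Optional[str] = None
    spec: Optional[SpecConfig] = None
    schedule: Optional[list[ScheduleEntryConfig]] = None
    machine: MachineConfig = MachineConfig()
    vo: VOConfig = VOConfig()
    is_method: ISConfig = Field(default=ISConfig(), alias="is")
    explore: ExploreConfig = ExploreConfig()
    fabrication: FabricationConfig = FabricationConfig()
    validation: ValidationConfig = ValidationConfig()

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def build_schedule(self) -> OffsetSchedule:
        if not self.schedule:
            raise ConfigError("config has no offset schedule")
        return OffsetSchedule(tuple((e.distance, e.role) for e in self.schedule))


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in exc.errors()]
        raise ConfigError("invalid config:\n  " + "\n  ".join(msgs)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = cfg.model_dump(by_alias=True, exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def example_path(name: str) -> Path:
    """Path of a shipped example config (growlay_hive2, clay_hive, demo)."""
    p = Path(__file__).parent / "examples" / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"no shipped example named {name!r}")
    return p
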