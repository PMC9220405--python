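"""Habitat and fabrication benchmarks for a scaffold model.

Feral honeybee colonies prefer nest cavities of 25 to 40 litres; a
full colony (about 60,000 workers plus queen, comb, honey and other
nest material) weighs up to 80 kg; the printer bounds module diameter
and height.  ``validate_design`` measures a model against a constraint
set and emits a machine-readable report, one entry per constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fabrication import MachineProfile, slice_into_modules
from .geometry_core import GeometryError, mesh_volume
from .is_pipeline import LoadCase, summarize_load_case
from .vo_pipeline import ScaffoldModel


@dataclass(frozen=True)
class ConstraintSet:
    cavity_volume_l: tuple[float, float] = (25.0, 40.0)
    entrance_diameter_mm: tuple[float, float] | None = None  # no field default: must be configured
    design_load_kgf: float = 80.0
    occupancy: int = 60_000
    machine: MachineProfile | None = None
    require_channel_continuity: bool = True

    def __post_init__(self):
        for name in ("cavity_volume_l", "entrance_diameter_mm"):
            pair = getattr(self, name)
            if pair is not None and pair[0] > pair[1]:
                raise GeometryError(f"{name}: lower bound exceeds upper bound")


@dataclass
class CheckResult:
    name: str
    measured: float | str
    bound: str
    passed: bool


@dataclass
class DesignReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps({
            "overall": "pass" if self.passed else "fail",
            "checks": [{"name": c.name, "measured": c.measured,
                        "bound": c.bound,
                        "result": "pass" if c.passed else "fail"}
                       for c in self.checks]}, indent=2)


def _in(value: float, bounds: tuple[float, float]) -> bool:
    return bounds[0] <= value <= bounds[1]  # inclusive


def validate_design(model: ScaffoldModel, constraints: ConstraintSet,
                    load_case: LoadCase | None = None) -> DesignReport:
    """Measure the model against every constraint in the set.

    Entrance bounds carry no field default (the feral-nest literature
    value is not fixed here); leaving them unset fails loudly rather
    than guessing.
    """
    rep = DesignReport()

    volume = mesh_volume(model.cavity_mesh)   # raises on open meshes
    lo, hi = constraints.cavity_volume_l
    rep.checks.append(CheckResult(
        "cavity_volume", round(volume, 3), f"[{lo}, {hi}] L",
        _in(volume, constraints.cavity_volume_l)))

    if constraints.entrance_diameter_mm is None:
        rep.checks.append(CheckResult(
            "entrance_diameter", "unconfigured",
            "entrance bounds must be configured", False))
    else:
        lo, hi = constraints.entrance_diameter_mm
        if model.entrance is None:
            rep.checks.append(CheckResult(
                "entrance_diameter", "absent", f"[{lo}, {hi}] mm", False))
        else:
            d = model.entrance.diameter
            rep.checks.append(CheckResult(
                "entrance_diameter", d, f"[{lo}, {hi}] mm",
                _in(d, constraints.entrance_diameter_mm)))

    if constraints.require_channel_continuity:
        ok = _channels_vertical(model)
        rep.checks.append(CheckResult(
            "channel_continuity", "vertical" if ok else "broken",
            "identical footprint across z-extent", ok))

    if constraints.machine is not None:
        try:
            modules = slice_into_modules(model, constraints.machine)
            h_max = max((m.z1 - m.z0) / 10.0 for m in modules)
            d_max = max(m.diameter for m in modules)
            ok_h = h_max <= constraints.machine.max_module_height + 1e-9
            ok_d = d_max <= constraints.machine.max_print_diameter + 1e-9
            rep.checks.append(CheckResult(
                "module_height", round(h_max, 2),
                f"<= {constraints.machine.max_module_height} cm", ok_h))
            rep.checks.append(CheckResult(
                "module_diameter", round(d_max, 2),
                f"<= {constraints.machine.max_print_diameter} cm", ok_d))
        except GeometryError as exc:
            rep.checks.append(CheckResult(
                "module_limits", str(exc), "machine limits", False))

    if load_case is not None:
        total = summarize_load_case(load_case)
        rep.checks.append(CheckResult(
            "design_load", round(total, 6),
            f"== {constraints.design_load_kgf} kgf",
            abs(total - constraints.design_load_kgf) < 1e-6))

    return rep


def _channels_vertical(model: ScaffoldModel) -> bool:
    """Every channel's reserved cell footprint must be identical on all
    layers of its z-extent (open vertical tubes for inoculation)."""
    for cid, (z0, z1) in model.channels.items():
        for pat in model.layers:
            if z0 - 1e-9 <= pat.z < z1 - 1e-9 and cid not in pat.channel_cells:
                return False
    return True
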