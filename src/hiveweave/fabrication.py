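"""From scaffold model to printer instructions.

A scaffold taller than the printer's safe build height is split into
stackable ring modules; clay parts are pre-scaled against drying/firing
shrinkage; each module's layers are emitted as G-code whose only
non-extruding moves are the layer changes — within a layer the weave
guarantees a single uninterrupted extrusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry_core import GeometryError, SolidMesh
from .units import cm_to_mm
from .vo_pipeline import ScaffoldModel, SlicePattern
from .weaving import Toolpath, continuity_check, path_length


@dataclass(frozen=True)
class MachineProfile:
    max_print_diameter: float = 40.0   # cm
    max_module_height: float = 15.0    # cm
    bead_width: float = 3.0            # mm
    layer_height: float = 2.0          # mm
    filament_diameter: float | None = None  # mm; None => paste extruder
    feed_rate: float = 30.0            # mm/s nominal, time estimates only

    def __post_init__(self):
        for name in ("max_print_diameter", "max_module_height", "bead_width",
                     "layer_height"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.bead_width < self.layer_height:
            raise GeometryError("bead width must be >= layer height")

    @property
    def paste_mode(self) -> bool:
        return self.filament_diameter is None

    def extrusion_per_mm(self) -> float:
        """E-register advance per mm of path (volumetric equality).

        Filament machines: path_mm * bead_w * layer_h / filament section.
        Paste machines: volumetric E at scale 1 (mm^3 per mm of path).
        """
        bead_section = self.bead_width * self.layer_height
        if self.paste_mode:
            return bead_section
        return bead_section / (np.pi * (self.filament_diameter / 2.0) ** 2)


@dataclass
class RingModule:
    index: int
    z0: float                         # mm, inclusive
    z1: float                         # mm, exclusive
    layers: list[SlicePattern]
    diameter: float                   # lateral bounding-circle diameter, cm


@dataclass(frozen=True)
class ShrinkageModel:
    """Linear shrink factor per axis (fraction of the fired dimension lost)."""
    factors: tuple[float, float, float]
    mode: str = "isotropic"

    @classmethod
    def isotropic(cls, factor: float) -> "ShrinkageModel":
        return cls((factor, factor, factor), "isotropic")

    def __post_init__(self):
        for f in self.factors:
            if not (0.0 <= f < 0.5):
                raise GeometryError("shrink factors must lie in [0, 0.5)")


def _layer_diameter(pattern: SlicePattern) -> float:
    """Lateral bounding-circle diameter of a slice, in cm."""
    r2max = 0.0
    if pattern.rings:               # outermost ring bounds the slice
        r2max = float(np.max(np.sum(pattern.rings[0].outer ** 2, axis=1)))
    else:                           # ring-less patterns: toolpath extents
        for tp in pattern.toolpaths:
            pts = tp.segments.reshape(-1, 2)
            r2max = max(r2max, float(np.max(np.sum(pts ** 2, axis=1))))
    return 2.0 * np.sqrt(r2max) / 10.0


def slice_into_modules(model: ScaffoldModel,
                       machine: MachineProfile) -> list[RingModule]:
    """Partition the scaffold into ring modules of printable height.

    Modules are uniform: count = ceil(total height / height limit),
    with boundaries snapped to layer boundaries; z-ranges are half-open
    [z0, z1) and exactly tile the scaffold's z-extent.
    """
    limit = cm_to_mm(machine.max_module_height)
    z_lo, z_hi = model.z_extent
    total = z_hi - z_lo
    n_modules = max(1, int(np.ceil(total / limit - 1e-9)))
    n_layers = len(model.layers)
    bounds = [z_lo + total * k / n_modules for k in range(n_modules + 1)]
    # snap interfaces to layer boundaries
    lh = model.layer_height
    bounds = [z_lo + round((b - z_lo) / lh) * lh for b in bounds]
    bounds[0], bounds[-1] = z_lo, z_hi
    # snapping may push a module over the limit by a fraction of a layer;
    # pull interfaces back to the largest whole-layer height within it
    cap = int(limit / lh + 1e-9) * lh
    for k in range(n_modules):
        if bounds[k + 1] - bounds[k] > cap + 1e-9:
            bounds[k + 1] = bounds[k] + cap
    if bounds[-1] < z_hi - 1e-9:
        raise GeometryError("cannot tile the scaffold height into "
                            f"{n_modules} modules under the height limit")
    bounds[-1] = z_hi

    modules = []
    for k in range(n_modules):
        lays = [p for p in model.layers if bounds[k] - 1e-9 <= p.z < bounds[k + 1] - 1e-9]
        dia = max((_layer_diameter(p) for p in lays), default=0.0)
        if dia > machine.max_print_diameter + 1e-9:
            worst = max(lays, key=_layer_diameter)
            raise GeometryError(
                f"layer {worst.layer} (z={worst.z} mm) has lateral diameter "
                f"{dia:.1f} cm > machine limit {machine.max_print_diameter} cm")
        if bounds[k + 1] - bounds[k] > limit + 1e-9:
            raise GeometryError(f"module {k} exceeds the height limit")
        modules.append(RingModule(k, bounds[k], bounds[k + 1], lays, dia))
    assert sum(len(m.layers) for m in modules) == n_layers
    return modules


def compensate_shrinkage(model: ScaffoldModel,
                         sh: ShrinkageModel) -> ScaffoldModel:
    """Pre-scale the model so the part shrinks back onto the design.

    Each axis is scaled by 1 / (1 - factor); applying the shrink to the
    compensated model reproduces the design within floating error.
    """
    gains = tuple(1.0 / (1.0 - f) for f in sh.factors)
    return _scale_model(model, gains)


def apply_shrinkage(model: ScaffoldModel, sh: ShrinkageModel) -> ScaffoldModel:
    """Simulate drying/firing: scale each axis by (1 - factor)."""
    return _scale_model(model, tuple(1.0 - f for f in sh.factors))


def _scale_model(model: ScaffoldModel, g: tuple[float, float, float]) -> ScaffoldModel:
    if abs(g[0] - g[1]) > 1e-12:
        raise GeometryError("per-axis in-plane factors must match "
                            "(toolpaths scale uniformly in x/y)")
    layers = []
    for p in model.layers:
        rings = [type(r)(r.outer * np.array(g[:2]),
                         tuple(h * np.array(g[:2]) for h in r.holes))
                 for r in p.rings]
        tps = [tp.scaled(g[0], g[1], g[2]) for tp in p.toolpaths]
        layers.append(SlicePattern(z=p.z * g[2], layer=p.layer, rings=rings,
                                   toolpaths=tps,
                                   channel_cells=p.channel_cells,
                                   weave_grids=p.weave_grids))
    return ScaffoldModel(
        layers=layers,
        cavity_mesh=model.cavity_mesh.scaled(g),
        enclosure_mesh=model.enclosure_mesh.scaled(g),
        channels={cid: (z0 * g[2], z1 * g[2])
                  for cid, (z0, z1) in model.channels.items()},
        layer_height=model.layer_height * g[2],
        spec=model.spec, entrance=model.entrance)


# ---------------------------------------------------------------------------
# G-code
# ---------------------------------------------------------------------------

_FMT = "{:.1f}"  # writer precision: 0.1 mm / 0.1 mm of extrusion


def to_gcode(modules: list[RingModule], machine: MachineProfile) -> list[str]:
    """Emit one Marlin-subset G-code text per module (absolute extrusion).

    Every toolpath must pass the continuity check; within a layer all
    moves extrude, and the approach move at each layer (or path) start
    is the only travel.
    """
    if not modules:
        raise GeometryError("no modules to emit")
    e_per_mm = machine.extrusion_per_mm()
    out = []
    for mod in modules:
        if not mod.layers or not any(p.toolpaths for p in mod.layers):
            raise GeometryError(f"module {mod.index} has no toolpaths")
        lines = [
            f"; hiveweave module {mod.index}  z=[{mod.z0:.1f},{mod.z1:.1f}) mm",
            "M82 ; absolute extrusion",
            "G92 E0",
        ]
        e = 0.0
        for pat in mod.layers:
            z_local = pat.z - mod.z0 + machine.layer_height
            for tp in pat.toolpaths:
                rep = continuity_check(tp)
                if not rep.continuous:
                    raise GeometryError(
                        f"layer {pat.layer}: discontinuous toolpath "
                        f"({rep.gap_count} gaps, max {rep.max_gap:.3f} mm, "
                        f"{rep.travel_segments} travel segments)")
                start = tp.segments[0, 0]
                lines.append(f"G0 X{_FMT.format(start[0])} "
                             f"Y{_FMT.format(start[1])} "
                             f"Z{_FMT.format(z_local)}")
                for (a, b) in tp.segments:
                    e += float(np.linalg.norm(b - a)) * e_per_mm
                    lines.append(f"G1 X{_FMT.format(b[0])} "
                                 f"Y{_FMT.format(b[1])} "
                                 f"E{e:.5f}")
        lines.append("; end of module")
        out.append("\n".join(lines) + "\n")
    return out


_G1_RE = re.compile(r"^G([01])\s+X(-?[\d.]+)\s+Y(-?[\d.]+)")


def parse_gcode_paths(gcode: str) -> list[np.ndarray]:
    """Recover the polyline vertices of each toolpath from emitted G-code."""
    paths: list[list[tuple[float, float]]] = []
    for line in gcode.splitlines():
        m = _G1_RE.match(line)
        if not m:
            continue
        kind, x, y = m.group(1), float(m.group(2)), float(m.group(3))
        if kind == "0":
            paths.append([(x, y)])
        elif paths:
            paths[-1].append((x, y))
    return [np.asarray(p) for p in paths if len(p) > 1]


def estimate_material(modules: list[RingModule], machine: MachineProfile,
                      density: float = 1.3) -> dict:
    """Path length (m), deposited bead volume (cm^3) and mass (g).

    density is the extruded material density in g/cm^3.
    """
    total_mm = 0.0
    for mod in modules:
        for pat in mod.layers:
            for tp in pat.toolpaths:
                total_mm += path_length(tp)
    vol_cm3 = total_mm * machine.bead_width * machine.layer_height / 1000.0
    return {
        "path_length_m": total_mm / 1000.0,
        "bead_volume_cm3": vol_cm3,
        "mass_g": vol_cm3 * density,
        "print_time_h": total_mm / machine.feed_rate / 3600.0,
    }
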