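"""Variable-offset (VO) scaffold generation.

A user contour is offset inward by a schedule of distances; each
schedule entry defines a concentric zone with a role:

* ``wall``   — a solid boundary, printed as the zone's outer perimeter;
* ``weave``  — the inter-offset space, filled with the continuous
  hexagonal weave (the porous body that mycelium colonises);
* ``channel``— a zone whose hexagonal cells are reserved as vertical
  tubular inoculation channels ("infill-feed"): no toolpath inside,
  identical cell footprint on every layer so the tubes stay open
  top-to-bottom for manual filling with inoculated substrate.

Stacking the resulting slice patterns with a constant layer height and
closing the inner contour into a watertight cavity mesh yields a full
hive scaffold: a warm dark nest space, a thickened woven roof above it
for moisture capture and insulation, an entrance bore with a landing
platform, and the channel registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .geometry_core import (GeometryError, PlanarRegion, SolidMesh,
                            offset_region)
from .hexgrid import HexGrid, annulus_grid, mesh_grid
from .units import cm_to_mm, litres_to_mm3, mm3_to_litres
from .weaving import Toolpath, weave


@dataclass(frozen=True)
class ScheduleEntry:
    distance: float          # zone width, mm
    role: str                # wall | weave | channel

    def __post_init__(self):
        if self.distance <= 0:
            raise GeometryError("schedule distances must be > 0")
        if self.role not in ("wall", "weave", "channel"):
            raise GeometryError(f"unknown zone role {self.role!r}")


@dataclass(frozen=True)
class OffsetSchedule:
    entries: tuple[ScheduleEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(
            e if isinstance(e, ScheduleEntry) else ScheduleEntry(*e)
            for e in self.entries))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def total_width(self) -> float:
        return sum(e.distance for e in self.entries)

    def require_wall(self) -> None:
        if not any(e.role == "wall" for e in self.entries):
            raise GeometryError("schedule must contain at least one wall zone")

    def check_channels(self, channel_diameter: float) -> None:
        for i, e in enumerate(self.entries):
            if e.role == "channel" and e.distance < channel_diameter:
                raise GeometryError(
                    f"channel zone {i} width {e.distance} mm is narrower than "
                    f"the channel diameter {channel_diameter} mm")


@dataclass(frozen=True)
class HiveSpec:
    """Habitat benchmarks for a standing hive.

    Volumes in litres and heights in cm at the config boundary; all
    derived geometry is millimetres.
    """

    cavity_target_volume: float       # L
    cavity_height: float              # cm
    entrance_diameter: float          # mm
    channel_diameter: float = 25.0    # mm
    roof_thickness: float = 60.0      # mm
    landing_platform: tuple[float, float] | None = (120.0, 80.0)  # length x width mm; None = attach-on part
    design_load: float = 80.0         # kgf: full colony + stores
    occupancy: int = 60_000           # worker count

    def __post_init__(self):
        if not (self.cavity_target_volume > 0 and np.isfinite(self.cavity_target_volume)):
            raise GeometryError("cavity_target_volume must be positive and finite")
        for name in ("cavity_height", "entrance_diameter", "channel_diameter",
                     "roof_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.design_load < 0:
            raise GeometryError("design_load must be >= 0")


@dataclass
class SlicePattern:
    z: float
    layer: int
    rings: list[PlanarRegion]               # outermost first, nested
    toolpaths: list[Toolpath]
    channel_cells: list[tuple[int, int]]
    weave_grids: list[HexGrid] = field(default_factory=list)


@dataclass
class Entrance:
    z_center: float          # mm
    diameter: float          # mm
    azimuth: float           # rad, direction of the bore
    bore_mesh: SolidMesh | None = None


@dataclass
class ScaffoldModel:
    layers: list[SlicePattern]
    cavity_mesh: SolidMesh
    enclosure_mesh: SolidMesh
    channels: dict[tuple[int, int], tuple[float, float]]  # cell id -> (z0, z1)
    layer_height: float
    spec: HiveSpec | None = None
    entrance: Entrance | None = None
    meta: dict = field(default_factory=dict)

    @property
    def z_extent(self) -> tuple[float, float]:
        return (self.layers[0].z, self.layers[-1].z + self.layer_height)

    @property
    def total_height(self) -> float:
        z0, z1 = self.z_extent
        return z1 - z0

    def cavity_volume(self) -> float:
        from .geometry_core import mesh_volume
        return mesh_volume(self.cavity_mesh)


def _single_region(regions: list[PlanarRegion], entry_idx: int) -> PlanarRegion:
    if not regions:
        raise GeometryError(
            f"offset schedule exhausts the contour at entry {entry_idx}")
    return max(regions, key=lambda r: r.area)


def generate_slice(contour: PlanarRegion, schedule: OffsetSchedule,
                   s: float, z: float = 0.0, layer: int = 0,
                   channel_cells=None, lattice_origin=(0.0, 0.0),
                   s_by_zone=None) -> SlicePattern:
    """One layer's rings, weave toolpaths and reserved channel cells.

    The hex lattice origin is shared across layers so that channel
    cells (and weave cells) are vertically aligned.
    """
    rings = [contour]
    toolpaths: list[Toolpath] = []
    grids: list[HexGrid] = []
    reserved: list[tuple[int, int]] = []
    for i, entry in enumerate(schedule):
        inner = _single_region(
            offset_region(rings[-1], entry.distance, "inward"), i)
        outer = rings[-1]
        if entry.role == "wall":
            toolpaths.append(Toolpath.from_polyline(
                outer.outer, z=z, layer=layer, closed=True,
                meta={"zone": i, "role": "wall"}))
        elif entry.role in ("weave", "channel"):
            zone_s = (s_by_zone or {}).get(i, s)
            grid = annulus_grid(outer, inner, zone_s, origin=lattice_origin)
            if entry.role == "weave":
                if len(grid):
                    if not grid.is_connected():
                        comps = grid.components()
                        for comp in sorted(comps, key=lambda c: min(c)):
                            sub = grid.subgrid(comp)
                            tp = weave(sub, z=z, layer=layer)
                            tp.meta["zone"] = i
                            toolpaths.append(tp)
                    else:
                        tp = weave(grid, z=z, layer=layer)
                        tp.meta["zone"] = i
                        toolpaths.append(tp)
                    grids.append(grid)
            else:  # channel
                if channel_cells is None:
                    reserved.extend(grid.ids)
        rings.append(inner)
    if channel_cells is not None:
        # fixed footprint supplied by the caller: identical on every layer
        reserved = list(channel_cells)
    return SlicePattern(z=z, layer=layer, rings=rings, toolpaths=toolpaths,
                        channel_cells=sorted(set(reserved)), weave_grids=grids)


# ---------------------------------------------------------------------------
# Cavity sizing
# ---------------------------------------------------------------------------

@dataclass
class CavityProfile:
    """Per-layer inner-contour radius of the nest cavity."""
    height: float            # mm
    base_radius: float       # mm
    top_radius: float        # mm

    def radius_at(self, z: float) -> float:
        t = np.clip(z / self.height, 0.0, 1.0)
        return (1 - t) * self.base_radius + t * self.top_radius


def solve_cavity_profile(spec: HiveSpec, shape: str = "cylinder",
                         taper_ratio: float = 1.0,
                         machine=None) -> CavityProfile:
    """Invert the target volume to contour radii.

    cylinder: r = sqrt(V / (pi h)). tapered: a conical frustum with
    top radius = taper_ratio * base radius, V = pi h (rb^2 + rb rt +
    rt^2) / 3 inverted for rb.
    """
    v_mm3 = litres_to_mm3(spec.cavity_target_volume)
    h = cm_to_mm(spec.cavity_height)
    if shape == "cylinder":
        rb = rt = float(np.sqrt(v_mm3 / (np.pi * h)))
    elif shape == "tapered":
        k = taper_ratio
        rb = float(np.sqrt(3 * v_mm3 / (np.pi * h * (1 + k + k * k))))
        rt = k * rb
    else:
        raise GeometryError(f"unknown cavity shape {shape!r}")
    if machine is not None:
        r_max = max(rb, rt)
        bed_mm = cm_to_mm(machine.max_print_diameter)
        if 2 * r_max > bed_mm:
            raise GeometryError(
                f"cavity radius {r_max:.1f} mm needs a print diameter of "
                f"{2 * r_max / 10:.1f} cm > machine limit "
                f"{machine.max_print_diameter} cm")
    return CavityProfile(height=h, base_radius=rb, top_radius=rt)


# ---------------------------------------------------------------------------
# Full hive generation
# ---------------------------------------------------------------------------

def _platform_contour(radius: float, platform: tuple[float, float],
                      azimuth: float, segments: int = 96) -> PlanarRegion:
    """Circle contour with a rectangular landing-platform protrusion."""
    circ = PlanarRegion.circle(radius, segments=segments, area_true=True)
    length, width = platform
    rect = box(0, -width / 2, radius + length, width / 2)
    from shapely import affinity
    rect = affinity.rotate(rect, np.rad2deg(azimuth), origin=(0, 0))
    merged = unary_union([circ.to_shapely(), rect])
    return PlanarRegion.from_shapely(merged)


def generate_hive(spec: HiveSpec, schedule: OffsetSchedule, machine,
                  s: float = 8.0, roof_layers: int | None = None,
                  roof_weave_scale: float = 1.5, shape: str = "cylinder",
                  taper_ratio: float = 1.0, entrance_azimuth: float = 0.0,
                  cavity_segments: int = 128) -> ScaffoldModel:
    """Generate a full VO hive scaffold.

    The cavity contour is solved from the target nest volume; the wall
    schedule is applied outward of it; the top ``roof_layers`` layers
    switch to a fully woven disc (the thick moisture-capturing roof);
    the entrance bore and landing platform sit just above the cavity
    floor. Identical layers share one computed slice pattern.
    """
    schedule.require_wall()
    schedule.check_channels(spec.channel_diameter)
    layer_h = machine.layer_height
    profile = solve_cavity_profile(spec, shape, taper_ratio, machine=machine)
    wall = schedule.total_width
    bed_mm = cm_to_mm(machine.max_print_diameter)
    r_outer_max = max(profile.base_radius, profile.top_radius) + wall
    if 2 * r_outer_max > bed_mm:
        raise GeometryError(
            f"outer diameter {2 * r_outer_max / 10:.1f} cm exceeds machine "
            f"bed {machine.max_print_diameter} cm by "
            f"{(2 * r_outer_max - bed_mm) / 10:.1f} cm")

    if roof_layers is None:
        roof_layers = max(1, int(round(spec.roof_thickness / layer_h)))
    n_cavity_layers = int(round(profile.height / layer_h))

    # entrance just above the cavity floor
    ent_z = spec.entrance_diameter / 2 + 2 * layer_h
    ent_lo = ent_z - spec.entrance_diameter / 2
    ent_hi = ent_z + spec.entrance_diameter / 2

    # channel cells: fixed once from the layer-0 contour so every layer
    # reserves the identical footprint (vertical tubes)
    s_channel = max(s, spec.channel_diameter / np.sqrt(3.0))
    chan_zone_s = {i: s_channel for i, e in enumerate(schedule)
                   if e.role == "channel"}
    base_contour = PlanarRegion.circle(profile.base_radius + wall,
                                       segments=cavity_segments, area_true=True)
    probe = generate_slice(base_contour, schedule, s, s_by_zone=chan_zone_s)
    channel_ids = probe.channel_cells

    total_h = n_cavity_layers * layer_h + roof_layers * layer_h
    layers: list[SlicePattern] = []
    cache: dict[tuple, SlicePattern] = {}
    for li in range(n_cavity_layers + roof_layers):
        z = li * layer_h
        in_roof = li >= n_cavity_layers
        in_entrance = (not in_roof) and (ent_lo <= z <= ent_hi) \
            and spec.landing_platform is not None
        if in_roof:
            r = profile.top_radius + wall
        else:
            r = profile.radius_at(z) + wall
        key = (round(r, 3), in_roof, in_entrance)
        if key in cache:
            src = cache[key]
            layers.append(SlicePattern(
                z=z, layer=li, rings=src.rings,
                toolpaths=[_rezet(tp, z, li) for tp in src.toolpaths],
                channel_cells=src.channel_cells, weave_grids=src.weave_grids))
            continue
        if in_entrance:
            contour = _platform_contour(r, spec.landing_platform,
                                        entrance_azimuth)
        else:
            contour = PlanarRegion.circle(r, segments=cavity_segments,
                                          area_true=True)
        if in_roof:
            pat = _roof_slice(contour, schedule, s * roof_weave_scale, z, li,
                              channel_ids, chan_zone_s)
        else:
            pat = generate_slice(contour, schedule, s, z=z, layer=li,
                                 channel_cells=channel_ids,
                                 s_by_zone=chan_zone_s)
        cache[key] = pat
        layers.append(pat)

    cavity_mesh = _cavity_mesh(profile, cavity_segments)
    r_enc = max(profile.base_radius, profile.top_radius) + wall
    enclosure = SolidMesh.cylinder(r_enc, total_h, segments=cavity_segments,
                                   center=(0, 0, total_h / 2), area_true=True)
    bore = SolidMesh.box(
        (wall * 2.5, spec.entrance_diameter, spec.entrance_diameter),
        center=(profile.radius_at(ent_z) + wall / 2, 0, ent_z))
    entrance = Entrance(z_center=ent_z, diameter=spec.entrance_diameter,
                        azimuth=entrance_azimuth, bore_mesh=bore)
    channels = {cid: (0.0, n_cavity_layers * layer_h) for cid in channel_ids}
    return ScaffoldModel(layers=layers, cavity_mesh=cavity_mesh,
                         enclosure_mesh=enclosure, channels=channels,
                         layer_height=layer_h, spec=spec, entrance=entrance)


def _rezet(tp: Toolpath, z: float, layer: int) -> Toolpath:
    out = Toolpath(tp.segments, tp.extrude, z, layer, tp.closed, dict(tp.meta))
    return out


def _roof_slice(contour: PlanarRegion, schedule: OffsetSchedule, s: float,
                z: float, layer: int, channel_ids, chan_zone_s) -> SlicePattern:
    """Roof layers: wall perimeter plus a fully woven interior disc."""
    wall_d = next(e.distance for e in schedule if e.role == "wall")
    inner = _single_region(offset_region(contour, wall_d, "inward"), 0)
    toolpaths = [Toolpath.from_polyline(contour.outer, z=z, layer=layer,
                                        closed=True, meta={"role": "wall"})]
    grid = mesh_grid(inner, s)
    grids = []
    if len(grid):
        for comp in (grid.components() if not grid.is_connected()
                     else [set(grid.ids)]):
            tp = weave(grid.subgrid(comp), z=z, layer=layer)
            tp.meta["role"] = "roof-weave"
            toolpaths.append(tp)
        grids.append(grid)
    return SlicePattern(z=z, layer=layer, rings=[contour, inner],
                        toolpaths=toolpaths, channel_cells=[],
                        weave_grids=grids)


def _cavity_mesh(profile: CavityProfile, segments: int) -> SolidMesh:
    if abs(profile.base_radius - profile.top_radius) < 1e-9:
        return SolidMesh.cylinder(profile.base_radius, profile.height,
                                  segments=segments,
                                  center=(0, 0, profile.height / 2),
                                  area_true=True)
    # frustum: lofted polygon prism, polygon areas matched to the circles
    import trimesh
    corr = 1.0 / np.sqrt(segments / (2 * np.pi) * np.sin(2 * np.pi / segments))
    ang = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    ring = np.c_[np.cos(ang), np.sin(ang)]
    vb = np.c_[ring * profile.base_radius * corr, np.zeros(segments)]
    vt = np.c_[ring * profile.top_radius * corr,
               np.full(segments, profile.height)]
    verts = np.vstack([vb, vt, [[0, 0, 0], [0, 0, profile.height]]])
    faces = []
    cb, ct = 2 * segments, 2 * segments + 1
    for i in range(segments):
        j = (i + 1) % segments
        faces += [[i, j, segments + i], [j, segments + j, segments + i],
                  [j, i, cb], [segments + i, segments + j, ct]]
    return SolidMesh(verts, np.asarray(faces))
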