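"""Planar and solid geometry primitives.

Planar regions are polygons with holes (outer ring counter-clockwise,
holes clockwise — normalized on construction). Solid geometry is
triangle meshes; volume queries require watertightness. shapely backs
all planar predicates and offsets, trimesh backs mesh bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .units import SNAP_TOL, mm3_to_litres


class GeometryError(ValueError):
    """Invalid geometric input (self-intersecting ring, open mesh, ...)."""


@dataclass(frozen=True)
class PlanarRegion:
    """A simple polygon with optional holes, coordinates in mm.

    The outer ring is stored counter-clockwise and holes clockwise;
    inputs in either orientation are normalized. Rings are stored
    without a repeated closing vertex.
    """

    outer: np.ndarray
    holes: tuple[np.ndarray, ...] = field(default_factory=tuple)

    def __post_init__(self):
        outer = _as_ring(self.outer)
        if _signed_area(outer) < 0:
            outer = outer[::-1]
        holes = []
        for h in self.holes:
            h = _as_ring(h)
            if _signed_area(h) > 0:
                h = h[::-1]
            holes.append(h)
        object.__setattr__(self, "outer", outer)
        object.__setattr__(self, "holes", tuple(holes))
        poly = self.to_shapely()
        if not poly.is_valid:
            raise GeometryError(f"invalid region: {shapely.is_valid_reason(poly)}")

    def to_shapely(self) -> Polygon:
        return Polygon(self.outer, [h for h in self.holes])

    @classmethod
    def from_shapely(cls, poly: Polygon) -> "PlanarRegion":
        outer = np.asarray(poly.exterior.coords)[:-1]
        holes = tuple(np.asarray(r.coords)[:-1] for r in poly.interiors)
        return cls(outer, holes)

    @classmethod
    def circle(cls, radius: float, center=(0.0, 0.0), segments: int = 64,
               area_true: bool = False) -> "PlanarRegion":
        """Regular polygon approximating a circle.

        With ``area_true`` the circumradius is inflated so the polygon
        area equals pi*radius^2 exactly (useful when a volume target is
        specified for the ideal circle).
        """
        r = radius
        if area_true:
            n = segments
            r = radius / np.sqrt(n / (2 * np.pi) * np.sin(2 * np.pi / n))
        ang = np.linspace(0, 2 * np.pi, segments, endpoint=False)
        pts = np.c_[center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
        return cls(pts)

    @property
    def area(self) -> float:
        return self.to_shapely().area

    def contains_point(self, x: float, y: float) -> bool:
        """Membership with boundary ties resolved to inside (snap tolerance)."""
        return self.to_shapely().buffer(SNAP_TOL).contains(shapely.Point(x, y))


def _as_ring(ring) -> np.ndarray:
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or len(ring) < 3:
        raise GeometryError("ring must be an (n>=3, 2) array")
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    return ring


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _regions_from_geom(geom) -> list[PlanarRegion]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:  # GeometryCollection from degenerate buffers
        polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return [PlanarRegion.from_shapely(p) for p in polys if p.area > SNAP_TOL]


def offset_region(region: PlanarRegion, distance: float,
                  direction: str = "inward") -> list[PlanarRegion]:
    """Offset a region's boundary by ``distance`` mm with round joins.

    Inward offsets may collapse the region (empty result) or split it
    into several components; both are reported as-is, not as errors.
    """
    if distance < 0:
        raise GeometryError("offset distance must be >= 0")
    if direction not in ("inward", "outward"):
        raise GeometryError(f"unknown offset direction {direction!r}")
    if distance == 0:
        return [region]
    sign = -1.0 if direction == "inward" else 1.0
    buffered = region.to_shapely().buffer(
        sign * distance, join_style="round", quad_segs=16)
    return _regions_from_geom(buffered)


def region_difference(outer: PlanarRegion, inner: PlanarRegion | None) -> list[PlanarRegion]:
    """outer minus inner, as a list of valid regions."""
    if inner is None:
        return [outer]
    return _regions_from_geom(outer.to_shapely().difference(inner.to_shapely()))


def regions_union(regions: list[PlanarRegion]) -> list[PlanarRegion]:
    return _regions_from_geom(unary_union([r.to_shapely() for r in regions]))


# ---------------------------------------------------------------------------
# Solid meshes
# ---------------------------------------------------------------------------

@dataclass
class SolidMesh:
    """Triangle mesh in mm, thin wrapper over trimesh."""

    vertices: np.ndarray
    faces: np.ndarray

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SolidMesh":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64))

    @classmethod
    def box(cls, extents, center=(0, 0, 0)) -> "SolidMesh":
        m = trimesh.creation.box(extents=extents)
        m.apply_translation(center)
        return cls.from_trimesh(m)

    @classmethod
    def cylinder(cls, radius: float, height: float, segments: int = 128,
                 center=(0.0, 0.0, 0.0), area_true: bool = False) -> "SolidMesh":
        """Prism over a regular polygon; see ``PlanarRegion.circle``."""
        r = radius
        if area_true:
            n = segments
            r = radius / np.sqrt(n / (2 * np.pi) * np.sin(2 * np.pi / n))
        m = trimesh.creation.cylinder(radius=r, height=height, sections=segments)
        m.apply_translation(center)
        return cls.from_trimesh(m)

    @classmethod
    def extrude_region(cls, region: PlanarRegion, height: float,
                       z0: float = 0.0) -> "SolidMesh":
        m = trimesh.creation.extrude_polygon(region.to_shapely(), height)
        m.apply_translation((0, 0, z0))
        return cls.from_trimesh(m)

    def scaled(self, factors) -> "SolidMesh":
        factors = np.broadcast_to(np.asarray(factors, dtype=float), (3,))
        return SolidMesh(self.vertices * factors, self.faces.copy())

    def save(self, path: str) -> None:
        self.to_trimesh().export(path)

    @classmethod
    def load(cls, path: str) -> "SolidMesh":
        return cls.from_trimesh(trimesh.load_mesh(path))


def mesh_volume(mesh: SolidMesh) -> float:
    """Enclosed volume in litres; requires a watertight mesh."""
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        edges = tm.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int(np.sum(counts != 2))
        raise GeometryError(
            f"mesh is not watertight: {n_open} edges not shared by exactly 2 faces")
    vol = tm.volume
    if vol < 0:
        vol = -vol  # inward-oriented input; magnitude is the enclosed volume
    return mm3_to_litres(float(vol))


def slice_solid(mesh: SolidMesh, z: float) -> list[PlanarRegion]:
    """Planar cross-section of a watertight mesh at height z (mm).

    Heights outside the mesh bounds give an empty list.
    """
    tm = mesh.to_trimesh()
    section = tm.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
    if section is None:
        return []
    planar, _ = section.to_2D(to_2D=np.array([[1, 0, 0, 0],
                                              [0, 1, 0, 0],
                                              [0, 0, 1, -z],
                                              [0, 0, 0, 1.0]], dtype=float))
    # assemble rings into polygons-with-holes by containment parity
    rings = [Polygon(c) for c in planar.discrete if len(c) >= 4]
    rings = [r if r.is_valid else r.buffer(0) for r in rings]
    rings = [r for r in rings if r.area > SNAP_TOL]
    depth = [sum(1 for o in rings if o is not r and o.contains(r))
             for r in rings]
    outers = [(r, i) for i, r in enumerate(rings) if depth[i] % 2 == 0]
    out = []
    for r, i in outers:
        holes = [h.exterior.coords for j, h in enumerate(rings)
                 if depth[j] == depth[i] + 1 and r.contains(h)]
        out.append(PlanarRegion.from_shapely(
            Polygon(r.exterior.coords, holes)))
    return out
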