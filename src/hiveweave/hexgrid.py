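"""Hexagonal cell lattices: the substrate of the weaving toolpath.

Cells live on a fixed pointy-top hexagonal lattice addressed by axial
coordinates (q, r); grids are formed by clipping the lattice to a
footprint (radial disc, arbitrary region, or annulus between two
regions). Membership is decided by the cell CENTER lying inside the
clip region, with boundary ties resolved to "inside" via the global
snap tolerance — this keeps weave zones between tight offsets
populated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry_core import GeometryError, PlanarRegion
from .units import SNAP_TOL

#: Axial neighbor directions, pointy-top convention.
AXIAL_DIRS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))

SQRT3 = np.sqrt(3.0)


def axial_to_xy(q: int, r: int, s: float, center=(0.0, 0.0),
                rotation: float = 0.0) -> tuple[float, float]:
    """Center of lattice cell (q, r) for circumradius s."""
    x = s * SQRT3 * (q + r / 2.0)
    y = s * 1.5 * r
    if rotation:
        c, sn = np.cos(rotation), np.sin(rotation)
        x, y = c * x - sn * y, sn * x + c * y
    return (center[0] + x, center[1] + y)


def hex_vertices(cx: float, cy: float, s: float,
                 rotation: float = 0.0) -> np.ndarray:
    """Six ordered vertices of a pointy-top hexagon of circumradius s."""
    ang = np.deg2rad(np.arange(30, 390, 60)) + rotation
    return np.c_[cx + s * np.cos(ang), cy + s * np.sin(ang)]


@dataclass(frozen=True)
class HexCell:
    q: int
    r: int
    center: tuple[float, float]
    s: float
    vertices: np.ndarray = field(repr=False)

    @property
    def id(self) -> tuple[int, int]:
        return (self.q, self.r)


class HexGrid:
    """A set of lattice cells with axial adjacency.

    Cells are keyed by their axial id (q, r). Adjacency is implied by
    the lattice: two cells are neighbors iff their axial ids differ by
    one of the six unit directions and both are present.
    """

    def __init__(self, cell_ids, s: float, origin=(0.0, 0.0),
                 rotation: float = 0.0, topology: str = "mesh"):
        if s <= 0:
            raise GeometryError("cell size s must be > 0")
        self.s = float(s)
        self.origin = (float(origin[0]), float(origin[1]))
        self.rotation = float(rotation)
        self.topology = topology
        self.cells: dict[tuple[int, int], HexCell] = {}
        for q, r in sorted(set(map(tuple, cell_ids))):
            cx, cy = axial_to_xy(q, r, s, self.origin, rotation)
            self.cells[(q, r)] = HexCell(q, r, (cx, cy), s,
                                         hex_vertices(cx, cy, s, rotation))

    def __len__(self) -> int:
        return len(self.cells)

    def __contains__(self, cell_id) -> bool:
        return tuple(cell_id) in self.cells

    def __iter__(self):
        return iter(self.cells.values())

    @property
    def ids(self) -> list[tuple[int, int]]:
        return list(self.cells.keys())

    def neighbors(self, cell_id) -> list[tuple[int, int]]:
        q, r = cell_id
        return [(q + dq, r + dr) for dq, dr in AXIAL_DIRS
                if (q + dq, r + dr) in self.cells]

    def is_connected(self) -> bool:
        return self.component_count() <= 1

    def component_count(self) -> int:
        return len(self.components())

    def components(self) -> list[set[tuple[int, int]]]:
        unseen = set(self.cells)
        comps = []
        while unseen:
            stack = [unseen.pop()]
            comp = set(stack)
            while stack:
                for nb in self.neighbors(stack.pop()):
                    if nb in unseen:
                        unseen.discard(nb)
                        comp.add(nb)
                        stack.append(nb)
            comps.append(comp)
        return comps

    def subgrid(self, cell_ids) -> "HexGrid":
        return HexGrid(cell_ids, self.s, self.origin, self.rotation, self.topology)

    # -- text fixture format ------------------------------------------------

    def dumps(self) -> str:
        out = io.StringIO()
        out.write(f"# hexgrid s={self.s} origin={self.origin[0]} {self.origin[1]} "
                  f"rotation={self.rotation} topology={self.topology}\n")
        for (q, r), cell in self.cells.items():
            nbs = ";".join(f"{a},{b}" for a, b in self.neighbors((q, r)))
            out.write(f"{q} {r} {cell.center[0]:.6f} {cell.center[1]:.6f} {nbs}\n")
        return out.getvalue()

    @classmethod
    def loads(cls, text: str) -> "HexGrid":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = dict(tok.split("=", 1) for tok in lines[0].lstrip("# ").split()
                      if "=" in tok)
        ox, oy = lines[0].split("origin=")[1].split()[:2]
        ids = []
        for ln in lines[1:]:
            parts = ln.split()
            ids.append((int(parts[0]), int(parts[1])))
        return cls(ids, float(header["s"]), (float(ox), float(oy)),
                   float(header["rotation"]), header.get("topology", "mesh"))


def radial_grid(rings: int, s: float, center=(0.0, 0.0),
                rotation: float = 0.0) -> HexGrid:
    """Hexagonal disc of the given ring count (3*rings*(rings+1)+1 cells)."""
    if rings < 0:
        raise GeometryError("rings must be >= 0")
    ids = [(q, r) for q in range(-rings, rings + 1)
           for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1)]
    return HexGrid(ids, s, center, rotation, topology="radial")


def _lattice_candidates(region: PlanarRegion, s: float, origin, rotation):
    """Axial id range whose centers could fall in the region's bbox."""
    minx, miny, maxx, maxy = region.to_shapely().bounds
    pad = 2 * s
    # invert the axial transform at the (rotated) bbox corners
    corners = [(minx - pad, miny - pad), (maxx + pad, miny - pad),
               (minx - pad, maxy + pad), (maxx + pad, maxy + pad)]
    qs, rs = [], []
    c, sn = np.cos(-rotation), np.sin(-rotation)
    for x, y in corners:
        x, y = x - origin[0], y - origin[1]
        x, y = c * x - sn * y, sn * x + c * y
        r = y / (1.5 * s)
        q = x / (SQRT3 * s) - r / 2.0
        qs.append(q)
        rs.append(r)
    return (int(np.floor(min(qs))) - 1, int(np.ceil(max(qs))) + 1,
            int(np.floor(min(rs))) - 1, int(np.ceil(max(rs))) + 1)


def mesh_grid(region: PlanarRegion, s: float, origin=(0.0, 0.0),
              rotation: float = 0.0) -> HexGrid:
    """Lattice cells whose centers lie inside the region (holes excluded)."""
    if s <= 0:
        raise GeometryError("cell size s must be > 0")
    q0, q1, r0, r1 = _lattice_candidates(region, s, origin, rotation)
    qs, rs = np.meshgrid(np.arange(q0, q1 + 1), np.arange(r0, r1 + 1),
                         indexing="ij")
    qs, rs = qs.ravel(), rs.ravel()
    xs = s * SQRT3 * (qs + rs / 2.0)
    ys = s * 1.5 * rs
    if rotation:
        c, sn = np.cos(rotation), np.sin(rotation)
        xs, ys = c * xs - sn * ys, sn * xs + c * ys
    xs, ys = xs + origin[0], ys + origin[1]
    clip = region.to_shapely().buffer(SNAP_TOL)
    shapely.prepare(clip)
    inside = shapely.contains_xy(clip, xs, ys)
    ids = list(zip(qs[inside].tolist(), rs[inside].tolist()))
    return HexGrid(ids, s, origin, rotation, topology="mesh")


def annulus_grid(outer: PlanarRegion, inner: PlanarRegion | None, s: float,
                 origin=(0.0, 0.0), rotation: float = 0.0) -> HexGrid:
    """Cells whose centers lie in ``outer`` minus ``inner`` (the weave zone)."""
    if inner is None:
        return mesh_grid(outer, s, origin, rotation)
    if not outer.to_shapely().buffer(SNAP_TOL).contains(inner.to_shapely()):
        raise GeometryError("inner region must lie strictly inside outer region")
    full = mesh_grid(outer, s, origin, rotation)
    hole = inner.to_shapely().buffer(SNAP_TOL)
    shapely.prepare(hole)
    cids = list(full.cells)
    ctrs = np.array([full.cells[c].center for c in cids])
    if len(ctrs) == 0:
        return full
    in_hole = shapely.contains_xy(hole, ctrs[:, 0], ctrs[:, 1])
    keep = [cid for cid, h in zip(cids, in_hole) if not h]
    g = full.subgrid(keep)
    g.topology = "mesh"
    return g
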