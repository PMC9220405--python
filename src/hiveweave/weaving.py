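"""Continuous hexagonal weaving: one uninterrupted extrusion polyline.

The weave traverses the control points (vertices) of every hexagonal
cell in a grid as a single closed stroke with no travel moves. It is
realized as a Hierholzer Eulerian-circuit walk on the cell-edge
multigraph: every cell contributes its six boundary edges, so an edge
shared by two cells appears twice (the doubled run is the "linear
bonding" feature), and every vertex receives an even degree from each
incident cell — a closed Eulerian circuit therefore exists on any
connected grid, by construction rather than by heuristic search.

Optional features:

* ``bead_width > 0`` bows the two passes of each doubled edge apart by
  a quarter bead width each, making the linear-bonding runs parallel
  rather than coincident and producing the point-bonding crossings at
  hexagon vertices.
* ``drape=True`` spans missing lattice cells: each absent cell with at
  least two present neighbors receives a doubled straight chord between
  its two farthest present vertices (doubling keeps degrees even, so
  continuity is preserved); the chord is extruded in free air across
  the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.strtree import STRtree

from .geometry_core import GeometryError
from .hexgrid import AXIAL_DIRS, HexGrid, axial_to_xy, hex_vertices
from .units import SNAP_TOL

_KEY_DECIMALS = 6  # vertex snap: 1e-6 mm


def _vkey(x: float, y: float) -> tuple[float, float]:
    return (round(x, _KEY_DECIMALS), round(y, _KEY_DECIMALS))


@dataclass
class Toolpath:
    """Ordered extrusion segments of one layer, coordinates in mm.

    Stored as an explicit segment list so that discontinuities (gaps,
    travel moves) are representable and detectable; a well-formed weave
    output is a closed chain of extruding segments.
    """

    segments: np.ndarray            # (M, 2, 2) xy endpoints
    extrude: np.ndarray             # (M,) bool
    z: float = 0.0
    layer: int = 0
    closed: bool = True
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_polyline(cls, points, z: float = 0.0, layer: int = 0,
                      closed: bool = True, meta=None) -> "Toolpath":
        pts = np.asarray(points, dtype=float)
        if closed and not np.allclose(pts[0], pts[-1]):
            pts = np.vstack([pts, pts[0]])
        segs = np.stack([pts[:-1], pts[1:]], axis=1)
        return cls(segs, np.ones(len(segs), dtype=bool), z, layer, closed,
                   meta or {})

    @property
    def vertices(self) -> np.ndarray:
        """Polyline vertices (valid for contiguous paths)."""
        return np.vstack([self.segments[:, 0], self.segments[-1, 1:]])

    def __len__(self) -> int:
        return len(self.segments)

    def scaled(self, fx: float, fy: float, fz: float) -> "Toolpath":
        segs = self.segments * np.array([fx, fy])
        return Toolpath(segs, self.extrude.copy(), self.z * fz, self.layer,
                        self.closed, dict(self.meta))

    def dumps(self) -> str:
        lines = [f"# toolpath layer={self.layer} z={self.z} closed={int(self.closed)}"]
        for (a, b), ext in zip(self.segments, self.extrude):
            lines.append(f"{a[0]:.6f} {a[1]:.6f} {b[0]:.6f} {b[1]:.6f} {int(ext)}")
        return "\n".join(lines) + "\n"


def path_length(path: Toolpath) -> float:
    """Total Euclidean length of all segments, in mm."""
    if len(path.segments) == 0:
        raise GeometryError("toolpath has no segments")
    d = path.segments[:, 1] - path.segments[:, 0]
    return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class ContinuityReport:
    continuous: bool
    gap_count: int
    max_gap: float
    travel_segments: int


def continuity_check(path: Toolpath, tol: float = SNAP_TOL) -> ContinuityReport:
    """Verify uninterrupted extrusion: every consecutive pair of segments
    shares an endpoint within ``tol`` and no non-extrusion segment exists."""
    if len(path.segments) == 0:
        raise GeometryError("empty toolpath")
    travel = int(np.sum(~path.extrude))
    ends = path.segments[:-1, 1]
    starts = path.segments[1:, 0]
    gaps = np.linalg.norm(ends - starts, axis=1)
    if path.closed and len(path.segments) > 1:
        gaps = np.append(gaps, np.linalg.norm(path.segments[-1, 1] -
                                              path.segments[0, 0]))
    open_gaps = gaps[gaps > tol]
    continuous = travel == 0 and len(open_gaps) == 0
    return ContinuityReport(continuous, int(len(open_gaps)),
                            float(open_gaps.max()) if len(open_gaps) else 0.0,
                            travel)


# ---------------------------------------------------------------------------
# Weave construction
# ---------------------------------------------------------------------------

def _cell_edges(cell):
    """Six (vkey_a, vkey_b, xy_a, xy_b) boundary edges of a cell."""
    v = cell.vertices
    out = []
    for i in range(6):
        a, b = v[i], v[(i + 1) % 6]
        out.append((_vkey(*a), _vkey(*b), a, b))
    return out


def _drape_chords(grid: HexGrid, present_vertices: set) -> list:
    """Doubled chords across missing lattice cells (drape zones)."""
    missing = {}
    for (q, r) in grid.cells:
        for dq, dr in AXIAL_DIRS:
            nb = (q + dq, r + dr)
            if nb not in grid.cells:
                missing[nb] = missing.get(nb, 0) + 1
    chords = []
    for (q, r), n_adj in sorted(missing.items()):
        # only enclosed holes (most neighbors present), not the exterior rim
        if n_adj < 4:
            continue
        cx, cy = axial_to_xy(q, r, grid.s, grid.origin, grid.rotation)
        verts = hex_vertices(cx, cy, grid.s, grid.rotation)
        keys = [(_vkey(*v), v) for v in verts]
        keys = [(k, v) for k, v in keys if k in present_vertices]
        if len(keys) < 2:
            continue
        best, best_d = None, -1.0
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = float(np.hypot(*(keys[i][1] - keys[j][1])))
                if d > best_d:
                    best_d, best = d, (keys[i], keys[j])
        (ka, va), (kb, vb) = best
        chords.append((ka, kb, va, vb))
    return chords


def weave(grid: HexGrid, start_cell=None, bead_width: float = 0.0,
          drape: bool = False, z: float = 0.0, layer: int = 0) -> Toolpath:
    """Single continuous extrusion polyline traversing every grid cell.

    Raises on an empty grid, and on a disconnected grid unless drape
    chords restore connectivity of the edge multigraph.
    """
    if len(grid) == 0:
        raise GeometryError("cannot weave an empty grid")

    # edge multigraph: vertex key -> list of [occurrence id]
    edge_occ = []            # (ka, kb, xy_a, xy_b, kind)
    edge_count: dict[tuple, int] = {}
    for cid in sorted(grid.cells):
        for ka, kb, a, b in _cell_edges(grid.cells[cid]):
            ekey = (min(ka, kb), max(ka, kb))
            edge_count[ekey] = edge_count.get(ekey, 0) + 1
            edge_occ.append((ka, kb, a, b, "edge"))

    present_vertices = {k for ka, kb, *_ in edge_occ for k in (ka, kb)}
    if drape:
        for ka, kb, a, b in _drape_chords(grid, present_vertices):
            for _ in range(2):  # doubled: keeps every degree even
                edge_occ.append((ka, kb, a, b, "drape"))

    adj: dict[tuple, list[int]] = {}
    for idx, (ka, kb, *_rest) in enumerate(edge_occ):
        adj.setdefault(ka, []).append(idx)
        adj.setdefault(kb, []).append(idx)
    for k in adj:
        adj[k].sort(key=lambda i: _other(edge_occ[i], k))

    # connectivity of the multigraph (drape chords may bridge cell components)
    n_comp = _vertex_components(adj, edge_occ)
    if n_comp > 1:
        raise GeometryError(
            f"grid is disconnected: {grid.component_count()} cell components "
            f"({n_comp} multigraph components); enable drape or fix the grid")

    if start_cell is None:
        start_cell = min(grid.cells)
    elif tuple(start_cell) not in grid.cells:
        raise GeometryError(f"start cell {start_cell} not in grid")
    start_vertex = min(_vkey(*v) for v in grid.cells[tuple(start_cell)].vertices)

    circuit = _hierholzer(adj, edge_occ, start_vertex)

    # traversal bookkeeping for feature detection / coverage checks
    traversed: dict[tuple, int] = {}
    pts = [np.asarray(circuit[0], dtype=float)]
    occ_seen: dict[tuple, int] = {}
    drape_segments = []
    for (k_from, k_to, occ_idx) in circuit[1]:
        ka, kb, a, b, kind = edge_occ[occ_idx]
        ekey = (min(ka, kb), max(ka, kb))
        traversed[ekey] = traversed.get(ekey, 0) + 1
        pass_no = occ_seen.get(ekey, 0)
        occ_seen[ekey] = pass_no + 1
        p_from = np.asarray(k_from, dtype=float)
        p_to = np.asarray(k_to, dtype=float)
        if kind == "drape":
            drape_segments.append(len(pts) - 1)
        if (bead_width > 0 and kind == "edge" and edge_count[ekey] == 2):
            # the two passes of a doubled edge run parallel, a quarter bead
            # to either side, and cut the corner at the hexagon vertices —
            # the corner-cut connectors of different passes cross there
            # (point bonding); exact endpoints are not emitted.
            side = 1.0 if pass_no == 0 else -1.0
            d = p_to - p_from
            length = np.linalg.norm(d)
            t = d / length
            n = np.array([-t[1], t[0]])
            inset = min(0.25 * length, bead_width)
            off = side * (bead_width / 4.0) * n
            pts.append(p_from + inset * t + off)
            pts.append(p_to - inset * t + off)
        else:
            pts.append(p_to)

    meta = {
        "grid_cells": sorted(grid.cells),
        "edge_traversals": traversed,
        "shared_edges": sum(1 for c in edge_count.values() if c == 2),
        "drape_chords": len({i for i in drape_segments}),
        "start_cell": tuple(start_cell),
        "bead_width": bead_width,
    }
    return Toolpath.from_polyline(pts, z=z, layer=layer, closed=True, meta=meta)


def _other(occ, k):
    return occ[1] if occ[0] == k else occ[0]


def _vertex_components(adj, edge_occ) -> int:
    unseen = set(adj)
    n = 0
    while unseen:
        n += 1
        stack = [unseen.pop()]
        while stack:
            v = stack.pop()
            for i in adj[v]:
                o = _other(edge_occ[i], v)
                if o in unseen:
                    unseen.discard(o)
                    stack.append(o)
    return n


def _hierholzer(adj, edge_occ, start):
    """Iterative Hierholzer circuit; ties broken by lowest neighbor key.

    Returns (start_vertex, [(from_key, to_key, occurrence_id), ...]).
    """
    used = [False] * len(edge_occ)
    ptr = {k: 0 for k in adj}
    stack = [start]
    circuit_vertices = []
    while stack:
        v = stack[-1]
        lst = adj[v]
        i = ptr[v]
        while i < len(lst) and used[lst[i]]:
            i += 1
        ptr[v] = i
        if i < len(lst):
            occ = lst[i]
            used[occ] = True
            stack.append(_other(edge_occ[occ], v))
        else:
            circuit_vertices.append(stack.pop())
    circuit_vertices.reverse()
    # recover one unused occurrence per consecutive vertex pair
    used2 = [False] * len(edge_occ)
    occ_by_pair: dict[tuple, list[int]] = {}
    for idx, (ka, kb, *_r) in enumerate(edge_occ):
        occ_by_pair.setdefault((min(ka, kb), max(ka, kb)), []).append(idx)
    edges = []
    for a, b in zip(circuit_vertices[:-1], circuit_vertices[1:]):
        key = (min(a, b), max(a, b))
        occ = next(i for i in occ_by_pair[key] if not used2[i])
        used2[occ] = True
        edges.append((a, b, occ))
    return circuit_vertices[0], edges


@dataclass
class WeaveFeatureReport:
    point_bonding: int
    linear_bonding: int
    drape_spans: int


def detect_features(path: Toolpath, grid: HexGrid) -> WeaveFeatureReport:
    """Count the weave's bonding/drape features.

    Linear bonding: interior (shared) cell edges, traversed twice by the
    stroke. Point bonding: transversal self-intersections of the path.
    Drape spans: segments whose midpoint lies outside every grid cell.
    """
    meta = path.meta
    if "edge_traversals" not in meta or meta.get("grid_cells") != sorted(grid.cells):
        raise GeometryError("toolpath was not generated from this grid")
    shared = _shared_edge_count(grid)
    doubled = sum(1 for v in meta["edge_traversals"].values() if v >= 2)
    if doubled < shared:
        raise GeometryError("traversal record inconsistent with grid adjacency")

    drape = 0
    cells = list(grid)
    centers = np.array([c.center for c in cells])
    for (a, b) in path.segments:
        mid = (a + b) / 2.0
        d2 = np.sum((centers - mid) ** 2, axis=1)
        near = np.argsort(d2)[:3]
        inside = any(
            Point(mid).within(ShapelyPolygon(cells[i].vertices).buffer(SNAP_TOL))
            for i in near)
        if not inside:
            drape += 1

    point = _transversal_crossings(path)
    return WeaveFeatureReport(point_bonding=point, linear_bonding=shared,
                              drape_spans=drape)


def _shared_edge_count(grid: HexGrid) -> int:
    n = 0
    for cid in grid.cells:
        n += len(grid.neighbors(cid))
    return n // 2


def _transversal_crossings(path: Toolpath) -> int:
    segs = [LineString([tuple(a), tuple(b)]) for a, b in path.segments
            if not np.allclose(a, b)]
    tree = STRtree(segs)
    pts = set()
    for i, s in enumerate(segs):
        for j in tree.query(s):
            j = int(j)
            if j <= i:
                continue
            inter = s.intersection(segs[j])
            if inter.is_empty or inter.geom_type != "Point":
                continue
            # transversal only: the crossing point is interior to both
            if (s.boundary.distance(inter) > SNAP_TOL and
                    segs[j].boundary.distance(inter) > SNAP_TOL):
                pts.add((round(inter.x, 4), round(inter.y, 4)))
    return len(pts)
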