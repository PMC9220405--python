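"""Deterministic test-surface generator.

Everything the test suite and the CLI demos consume — toy contours,
box domains, random-but-seeded star polygons and connected hex grids,
canonical load cases — is generated here rather than shipped as data.
"""

from __future__ import annotations

import numpy as np

from .geometry_core import GeometryError, PlanarRegion
from .hexgrid import AXIAL_DIRS, HexGrid, radial_grid
from .is_pipeline import LoadCase


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a named fixture; deterministic for fixed (params, seed)."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    builders = {
        "contour": _contour,
        "domain": _domain,
        "grid": _grid,
        "loadcase": _loadcase,
    }
    if kind not in builders:
        raise GeometryError(f"unknown fixture kind {kind!r}; "
                            f"expected one of {sorted(builders)}")
    return builders[kind](params, rng)


def _contour(params, rng):
    shape = params.pop("shape", "circle")
    if shape == "circle":
        r = params.pop("radius", 100.0)
        segments = params.pop("segments", 64)
        return PlanarRegion.circle(r, segments=segments)
    if shape == "rounded_rect":
        w = params.pop("width", 200.0)
        h = params.pop("height", 150.0)
        cr = params.pop("corner_radius", 20.0)
        from shapely.geometry import box
        poly = box(-w / 2 + cr, -h / 2 + cr, w / 2 - cr, h / 2 - cr).buffer(
            cr, quad_segs=8)
        return PlanarRegion.from_shapely(poly)
    if shape == "star":
        n = params.pop("points", 12)
        r_out = params.pop("radius", 100.0)
        jitter = params.pop("jitter", 0.3)
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        radii = r_out * (1 - jitter * rng.random(n))
        return PlanarRegion(np.c_[radii * np.cos(ang), radii * np.sin(ang)])
    raise GeometryError(f"unknown contour shape {shape!r}")


def _domain(params, rng):
    dims = tuple(params.pop("dims", (16, 16, 12)))
    edge = params.pop("edge", 10.0)
    from .is_pipeline import VoxelField
    return VoxelField.uniform(dims, edge, params.pop("value", 1.0))


def _grid(params, rng):
    kind = params.pop("shape", "radial")
    s = params.pop("s", 6.0)
    if kind == "radial":
        return radial_grid(params.pop("rings", 2), s)
    if kind == "random_connected":
        # seeded random walk over the lattice: always one component
        n = int(params.pop("cells", 40))
        cells = {(0, 0)}
        frontier = [(0, 0)]
        while len(cells) < n:
            q, r = frontier[rng.integers(len(frontier))]
            dq, dr = AXIAL_DIRS[rng.integers(6)]
            nb = (q + dq, r + dr)
            if nb not in cells:
                cells.add(nb)
                frontier.append(nb)
        return HexGrid(sorted(cells), s)
    raise GeometryError(f"unknown grid shape {kind!r}")


def _loadcase(params, rng):
    kind = params.pop("shape", "cantilever")
    if kind == "cantilever":
        nx = int(params.pop("nx", 8))
        ny = int(params.pop("ny", 5))
        load = params.pop("load", 10.0)
        return LoadCase(
            loads=[((nx - 1, 0), (0.0, -1.0), load)],
            supports=[(0, j) for j in range(ny)],
            volume_fraction=params.pop("volume_fraction", 0.4),
            penalization=params.pop("penalization", 3.0),
            filter_radius=params.pop("filter_radius", 1.5))
    if kind == "colony-floor":
        # full-colony weight on the center of the top face, fixed base
        dims = tuple(params.pop("dims", (16, 16, 12)))
        total = params.pop("load", 80.0)
        nx, ny, nz = dims
        sx = range(nx // 2 - nx // 4, nx // 2 + nx // 4)
        sy = range(ny // 2 - ny // 4, ny // 2 + ny // 4)
        patch = [(i, j, nz - 1) for i in sx for j in sy]
        return LoadCase(
            loads=[(v, (0.0, 0.0, -1.0), total / len(patch)) for v in patch],
            supports=[(i, j, 0) for i in range(nx) for j in range(ny)],
            volume_fraction=params.pop("volume_fraction", 0.45),
            penalization=params.pop("penalization", 3.0),
            filter_radius=params.pop("filter_radius", 1.5))
    raise GeometryError(f"unknown load case shape {kind!r}")
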