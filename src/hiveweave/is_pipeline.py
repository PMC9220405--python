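"""Iterative-subtraction (IS) scaffold generation.

Material is distributed over a voxelised design domain by density-based
topology optimization (SIMP: Solid Isotropic Material with
Penalization): linear-elastic finite elements (4-node quads in 2D test
mode, 8-node hexahedra in 3D) with modified-SIMP stiffness
interpolation E(rho) = Emin + rho^p (E0 - Emin), compliance sensitivity
filtering, and an optimality-criteria update whose Lagrange multiplier
is found by bisection so the volume-fraction constraint is met exactly
at every iterate.  Plain optimization yields near-uniform porosity, so
geometric attractors (points or lines) may then superpose density
gradients.  The field is thresholded and each voxel layer is replaced
by hexagonal cells, which the continuous weave traverses; a nest cavity
is finally carved from the densest region (enclosed variant) or opened
to the sky (open variant).

Elements are unit cubes/squares in the FEM (the conventional
normalisation: the density field is invariant to uniform element
scaling and to load magnitude); the voxel edge length carries the
physical scale for all geometry built from the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry_core import GeometryError, SolidMesh
from .hexgrid import HexGrid
from .units import kgf_to_newton, newton_to_kgf
from .vo_pipeline import ScaffoldModel, SlicePattern
from .weaving import weave

E0 = 1.0
EMIN = 1e-9
NU = 0.3


@dataclass
class VoxelField:
    """Density field rho in [0,1] over an (nx, ny[, nz]) voxel grid.

    Voxel (0,0,0) is centered half an edge length from the domain
    corner; flat ordering is x-fastest.
    """

    dims: tuple[int, ...]
    edge: float                    # mm
    rho: np.ndarray                # shape dims (Fortran-like semantics via index order)

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise GeometryError("voxel dims must be >= 1")
        self.rho = np.asarray(self.rho, dtype=float).reshape(self.dims, order="F")
        if self.rho.min() < -1e-12 or self.rho.max() > 1 + 1e-12:
            raise GeometryError("densities must lie in [0, 1]")

    @classmethod
    def uniform(cls, dims, edge: float, value: float) -> "VoxelField":
        return cls(tuple(dims), edge, np.full(tuple(dims), value, order="F"))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    def centers(self) -> np.ndarray:
        """Voxel centers in mm, shape (n_voxels, ndim), x-fastest order."""
        axes = [np.arange(d) + 0.5 for d in self.dims]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel(order="F") for m in mesh], axis=1) * self.edge

    def copy(self) -> "VoxelField":
        return VoxelField(self.dims, self.edge, self.rho.copy())


@dataclass
class LoadCase:
    """Loads, supports and optimization settings on a voxel domain.

    Load magnitudes are given in kgf (the colony is weighed in kg) and
    converted to newtons internally; each load is distributed equally
    over the corner nodes of its voxel.  Support voxels have all their
    corner nodes fully fixed.
    """

    loads: list[tuple[tuple[int, ...], tuple[float, ...], float]]  # (voxel, direction, kgf)
    supports: list[tuple[int, ...]]
    volume_fraction: float
    penalization: float = 3.0
    filter_radius: float = 1.5     # in voxel units

    def __post_init__(self):
        if not self.loads or not self.supports:
            raise GeometryError("a load case needs at least one load and one support")
        if not (0.0 < self.volume_fraction <= 1.0):
            raise GeometryError("volume fraction must lie in (0, 1]")

    def total_load_kgf(self) -> float:
        return float(sum(m for _, _, m in self.loads))


def summarize_load_case(case: LoadCase) -> float:
    """Total applied load, reported back in kgf."""
    total_n = sum(kgf_to_newton(m) for _, _, m in case.loads)
    return newton_to_kgf(total_n)


@dataclass(frozen=True)
class Attractor:
    kind: str                     # point | line
    geometry: tuple               # point: (x,y[,z]); line: (p0, p1)
    strength: float = 0.5
    falloff: float = 50.0         # mm

    def __post_init__(self):
        if self.kind not in ("point", "line"):
            raise GeometryError(f"unknown attractor kind {self.kind!r}")
        if self.strength < 0 or self.falloff < 0:
            raise GeometryError("attractor strength and falloff must be >= 0")

    def distance(self, pts: np.ndarray) -> np.ndarray:
        if self.kind == "point":
            p = np.asarray(self.geometry, dtype=float)
            return np.linalg.norm(pts - p, axis=1)
        p0 = np.asarray(self.geometry[0], dtype=float)
        p1 = np.asarray(self.geometry[1], dtype=float)
        d = p1 - p0
        t = np.clip((pts - p0) @ d / (d @ d), 0.0, 1.0)
        return np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)


# ---------------------------------------------------------------------------
# Finite elements (unit elements, 2x2(x2) Gauss quadrature)
# ---------------------------------------------------------------------------

def element_stiffness(ndim: int, nu: float = NU) -> np.ndarray:
    """Stiffness of a unit bilinear quad (plane stress) or trilinear hex."""
    if ndim == 2:
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = (1.0 / (1 - nu * nu)) * np.array(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
        ngauss, nstrain, ndof = 2, 3, 8
    else:
        corners = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                           dtype=float)
        lam = nu / ((1 + nu) * (1 - 2 * nu))
        mu = 1.0 / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[3:, 3:] = np.eye(3) * mu
        ngauss, nstrain, ndof = 2, 6, 24
    gp = np.array([-1, 1]) / np.sqrt(3.0)
    K = np.zeros((ndof, ndof))
    for pt in np.stack(np.meshgrid(*([gp] * ndim), indexing="ij"),
                       axis=-1).reshape(-1, ndim):
        dN = _shape_gradients(corners, pt, ndim)      # (ncorner, ndim), unit element
        B = np.zeros((nstrain, ndof))
        for a in range(len(corners)):
            if ndim == 2:
                B[0, 2 * a] = dN[a, 0]
                B[1, 2 * a + 1] = dN[a, 1]
                B[2, 2 * a] = dN[a, 1]
                B[2, 2 * a + 1] = dN[a, 0]
            else:
                B[0, 3 * a] = dN[a, 0]
                B[1, 3 * a + 1] = dN[a, 1]
                B[2, 3 * a + 2] = dN[a, 2]
                B[3, 3 * a] = dN[a, 1]
                B[3, 3 * a + 1] = dN[a, 0]
                B[4, 3 * a + 1] = dN[a, 2]
                B[4, 3 * a + 2] = dN[a, 1]
                B[5, 3 * a] = dN[a, 2]
                B[5, 3 * a + 2] = dN[a, 0]
        K += (B.T @ D @ B) * (0.5 ** ndim)   # |J| of unit element at 2-pt Gauss
    return K


def _shape_gradients(corners: np.ndarray, xi: np.ndarray, ndim: int) -> np.ndarray:
    """Cartesian gradients of the (bi/tri)linear shape functions on the
    unit element at natural point xi in [-1,1]^ndim."""
    signs = corners * 2 - 1
    grads = np.zeros_like(corners)
    for a, s in enumerate(signs):
        for d in range(ndim):
            g = 0.5 * s[d]          # d/dxi of (1 + s*xi)/2, times jacobian 2/h=2
            for o in range(ndim):
                if o != d:
                    g *= 0.5 * (1 + s[o] * xi[o])
            grads[a, d] = g * 2.0   # unit element: dxi/dx = 2
    return grads


def _node_index(dims, pt):
    """Node id for integer node coordinates, x-fastest."""
    if len(dims) == 2:
        nx, ny = dims
        return pt[0] + pt[1] * (nx + 1)
    nx, ny, nz = dims
    return pt[0] + pt[1] * (nx + 1) + pt[2] * (nx + 1) * (ny + 1)


def _element_dofs(dims):
    """(n_elements, ndof) dof gather array, element order x-fastest."""
    ndim = len(dims)
    if ndim == 2:
        offsets = [(0, 0), (1, 0), (1, 1), (0, 1)]
        ex, ey = np.meshgrid(np.arange(dims[0]), np.arange(dims[1]),
                             indexing="ij")
        elems = np.stack([ex.ravel(order="F"), ey.ravel(order="F")], axis=1)
    else:
        offsets = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                   (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
        ex, ey, ez = np.meshgrid(np.arange(dims[0]), np.arange(dims[1]),
                                 np.arange(dims[2]), indexing="ij")
        elems = np.stack([ex.ravel(order="F"), ey.ravel(order="F"),
                          ez.ravel(order="F")], axis=1)
    dofs = np.zeros((len(elems), len(offsets) * ndim), dtype=np.int64)
    for a, off in enumerate(offsets):
        nid = _node_index(dims, (elems[:, 0] + off[0], elems[:, 1] + off[1])
                          if ndim == 2 else
                          (elems[:, 0] + off[0], elems[:, 1] + off[1],
                           elems[:, 2] + off[2]))
        for d in range(ndim):
            dofs[:, a * ndim + d] = ndim * nid + d
    return elems, dofs


def _filter_matrix(dims, rmin: float) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse cone-kernel weights between element centers within rmin."""
    ndim = len(dims)
    axes = [np.arange(d) + 0.5 for d in dims]
    mesh = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([m.ravel(order="F") for m in mesh], axis=1)
    n = len(centers)
    reach = int(np.ceil(rmin))
    rows, cols, vals = [], [], []
    grid_index = np.arange(n).reshape(dims, order="F")
    for i in range(n):
        c = centers[i]
        lo = [max(0, int(c[d] - 0.5) - reach) for d in range(ndim)]
        hi = [min(dims[d], int(c[d] - 0.5) + reach + 1) for d in range(ndim)]
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        nbrs = grid_index[sl].ravel(order="F")
        w = rmin - np.linalg.norm(centers[nbrs] - c, axis=1)
        keep = w > 0
        rows.extend([i] * int(keep.sum()))
        cols.extend(nbrs[keep])
        vals.extend(w[keep])
    H = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return H, np.asarray(H.sum(axis=1)).ravel()


class _FEModel:
    """Assembled SIMP FEM on a voxel domain; reused across iterations."""

    def __init__(self, dims, case: LoadCase):
        self.dims = tuple(dims)
        self.ndim = len(self.dims)
        self.KE = element_stiffness(self.ndim)
        self.elems, self.edofs = _element_dofs(self.dims)
        n_nodes = np.prod([d + 1 for d in self.dims])
        self.ndof = int(self.ndim * n_nodes)
        self.F = np.zeros(self.ndof)
        ncorner = 2 ** self.ndim
        elem_ids = {tuple(e): k for k, e in enumerate(self.elems)}
        for voxel, direction, kgf in case.loads:
            voxel = tuple(int(v) for v in voxel)
            if voxel not in elem_ids:
                raise GeometryError(f"load voxel {voxel} outside domain {self.dims}")
            vec = np.asarray(direction, dtype=float)
            vec = vec / np.linalg.norm(vec) * kgf_to_newton(kgf) / ncorner
            dofs = self.edofs[elem_ids[voxel]]
            for a in range(ncorner):
                for d in range(self.ndim):
                    self.F[dofs[a * self.ndim + d]] += vec[d]
        fixed = set()
        for voxel in case.supports:
            voxel = tuple(int(v) for v in voxel)
            if voxel not in elem_ids:
                raise GeometryError(f"support voxel {voxel} outside domain {self.dims}")
            fixed.update(self.edofs[elem_ids[voxel]].tolist())
        self.fixed = np.array(sorted(fixed), dtype=np.int64)
        self.free = np.setdiff1d(np.arange(self.ndof), self.fixed)
        # constant assembly pattern
        ndof_e = self.edofs.shape[1]
        self._rows = np.repeat(self.edofs, ndof_e, axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, ndof_e)).ravel()

    def solve(self, x: np.ndarray, p: float) -> tuple[np.ndarray, float, np.ndarray]:
        """Displacements, compliance and per-element compliance energy."""
        E = EMIN + x ** p * (E0 - EMIN)
        vals = (self.KE.ravel()[None, :] * E[:, None]).ravel()
        K = sp.csr_matrix((vals, (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof))
        Kff = K[self.free][:, self.free]
        U = np.zeros(self.ndof)
        try:
            U[self.free] = spla.spsolve(Kff.tocsc(), self.F[self.free])
        except RuntimeError as exc:  # singular factorization
            raise GeometryError(
                f"singular stiffness system (floating structure): {exc}") from exc
        if not np.all(np.isfinite(U)):
            bad = int(np.sum(~np.isfinite(U)))
            raise GeometryError(
                f"singular stiffness system: {bad} unconstrained degrees of freedom")
        Ue = U[self.edofs]
        ce = np.einsum("ij,jk,ik->i", Ue, self.KE, Ue)
        comp = float(E @ ce)
        return U, comp, ce


def _oc_update(x, dc, dv, f, move=0.2, tol=1e-10):
    """Optimality-criteria step; bisection on the Lagrange multiplier
    keeps the volume fraction exact."""
    l1, l2 = 0.0, 1e9
    xnew = x
    while (l2 - l1) / (l1 + l2 + 1e-30) > tol:
        lmid = 0.5 * (l1 + l2)
        step = x * np.sqrt(np.maximum(-dc, 0.0) / (dv * lmid))
        xnew = np.clip(step, np.maximum(0.0, x - move), np.minimum(1.0, x + move))
        if xnew.mean() - f > 0:
            l1 = lmid
        else:
            l2 = lmid
    return xnew


def simp_optimize(dims, case: LoadCase, iterations: int = 30,
                  edge: float = 10.0, filter_mode: str = "sensitivity",
                  callback=None) -> tuple[VoxelField, list[float]]:
    """SIMP compliance minimisation under a volume-fraction constraint.

    Returns the optimized density field and the compliance history
    (one entry per iteration).  Deterministic: no random state.
    """
    if iterations < 1:
        raise GeometryError("iterations must be >= 1")
    dims = tuple(int(d) for d in dims)
    model = _FEModel(dims, case)
    H, Hs = _filter_matrix(dims, case.filter_radius)
    f = case.volume_fraction
    p = case.penalization
    x = np.full(int(np.prod(dims)), f)
    history: list[float] = []
    for it in range(iterations):
        xphys = H @ x / Hs if filter_mode == "density" else x
        _, comp, ce = model.solve(xphys, p)
        history.append(comp)
        dc = -p * xphys ** (p - 1) * (E0 - EMIN) * ce
        dv = np.ones_like(x)
        if filter_mode == "sensitivity":
            dc = (H @ (x * dc)) / (Hs * np.maximum(1e-3, x))
        elif filter_mode == "density":
            dc = H.T @ (dc / Hs)
            dv = H.T @ (dv / Hs)
        else:
            raise GeometryError(f"unknown filter mode {filter_mode!r}")
        x = _oc_update(x, dc, dv, f)
        if callback is not None:
            callback(it, x, comp)
    xphys = H @ x / Hs if filter_mode == "density" else x
    field = VoxelField(dims, edge, np.clip(xphys, 0.0, 1.0))
    return field, history


def apply_attractors(field: VoxelField, attractors: list[Attractor]) -> VoxelField:
    """Superpose attractor density gradients:
    rho' = clamp(rho + strength * max(0, 1 - d/falloff), 0, 1)."""
    if not attractors:
        return field.copy()
    rho = field.rho.ravel(order="F").copy()
    pts = field.centers()
    for att in attractors:
        d = att.distance(pts)
        if att.falloff > 0:
            boost = att.strength * np.maximum(0.0, 1.0 - d / att.falloff)
        else:
            boost = np.where(d <= 0, att.strength, 0.0)
        rho = rho + boost
    return VoxelField(field.dims, field.edge, np.clip(rho, 0.0, 1.0))


def voxels_to_hexcells(field: VoxelField, threshold: float,
                       s: float | None = None) -> list[HexGrid]:
    """Replace above-threshold voxels with hexagonal cells, layer by layer.

    The mapping voxel (i, j) -> axial (i - (j - (j & 1)) // 2, j) is
    one-to-one ("odd-r" offset coordinates), so each layer's cell count
    equals its above-threshold voxel count exactly.  Default cell size
    makes the lattice pitch equal the voxel edge.
    """
    if not (0.0 < threshold < 1.0):
        raise GeometryError("threshold must lie in (0, 1)")
    if s is None:
        s = field.edge / np.sqrt(3.0)
    rho = field.rho if field.ndim == 3 else field.rho[..., None]
    nz = rho.shape[2]
    grids = []
    for k in range(nz):
        mask = rho[:, :, k] >= threshold
        ids = [(int(i - (j - (j & 1)) // 2), int(j))
               for i, j in zip(*np.nonzero(mask))]
        grids.append(HexGrid(ids, s))
    return grids


def is_generate(spec, case: LoadCase, variant: str = "enclosed",
                dims=(16, 16, 12), edge: float | None = None,
                iterations: int = 15, attractors: list[Attractor] = (),
                threshold: float = 0.5,
                feed_mode: str = "infill") -> ScaffoldModel:
    """Full IS scaffold: optimize, shape, threshold, carve, weave.

    ``enclosed`` carves a closed nest cavity of the spec volume out of
    the domain center; ``open`` carves an upward-open recess meeting
    the top boundary.  ``feed_mode='self'`` halves the weave cell size
    (the nutritionally printable, higher-resolution preset).
    """
    if variant not in ("enclosed", "open"):
        raise GeometryError(f"unknown IS variant {variant!r}")
    from .units import cm_to_mm, litres_to_mm3
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3:
        raise GeometryError("is_generate needs a 3D domain")
    cav_h = cm_to_mm(spec.cavity_height)
    v_mm3 = litres_to_mm3(spec.cavity_target_volume)
    cav_r = float(np.sqrt(v_mm3 / (np.pi * cav_h)))
    if edge is None:
        # size the domain to hold the cavity with a one-third margin
        edge = max(2.5 * cav_r / dims[0], 1.4 * cav_h / dims[2])

    field, history = simp_optimize(dims, case, iterations=iterations, edge=edge)
    field = apply_attractors(field, list(attractors))
    grids = voxels_to_hexcells(field, threshold,
                               s=(field.edge / np.sqrt(3.0) / 2.0
                                  if feed_mode == "self" else None))

    cx = dims[0] * edge / 2.0
    cy = dims[1] * edge / 2.0
    total_h = dims[2] * edge
    if variant == "enclosed":
        z0 = (total_h - cav_h) / 2.0
        z1 = z0 + cav_h
    else:
        z1 = total_h + edge          # recess pierces the top boundary
        z0 = total_h - cav_h
    carved_layers: list[SlicePattern] = []
    split_report = []
    for k, grid in enumerate(grids):
        z = (k + 0.5) * edge
        if z0 <= z <= z1 and len(grid):
            keep = [cid for cid, cell in grid.cells.items()
                    if (cell.center[0] - cx) ** 2 + (cell.center[1] - cy) ** 2
                    > cav_r ** 2]
            grid = grid.subgrid(keep)
        toolpaths = []
        if len(grid):
            comps = grid.components()
            if len(comps) > 1:
                split_report.append((k, len(comps)))
            for comp in sorted(comps, key=min):
                toolpaths.append(weave(grid.subgrid(comp), z=z, layer=k))
        carved_layers.append(SlicePattern(z=k * edge, layer=k, rings=[],
                                          toolpaths=toolpaths,
                                          channel_cells=[],
                                          weave_grids=[grid] if len(grid) else []))

    cavity_mesh = SolidMesh.cylinder(
        cav_r, cav_h, segments=96, area_true=True,
        center=(cx, cy, (z0 + min(z1, total_h)) / 2.0 if variant == "enclosed"
                else z0 + cav_h / 2.0))
    enclosure = SolidMesh.box((dims[0] * edge, dims[1] * edge, total_h),
                              center=(cx, cy, total_h / 2.0))
    return ScaffoldModel(
        layers=carved_layers, cavity_mesh=cavity_mesh,
        enclosure_mesh=enclosure, channels={}, layer_height=edge, spec=spec,
        meta={"variant": variant, "splits": split_report,
              "compliance_history": history,
              "total_load_kgf": summarize_load_case(case)})
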