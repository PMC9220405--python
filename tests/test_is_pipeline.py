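"""Topology optimization, attractor gradients and voxel-to-hexcell
translation.

The oracle for the optimizer is a deliberately naive, dense, loop-based
optimality-criteria implementation whose element stiffness is derived
by exact symbolic integration (sympy) — independent of the package's
vectorized sparse assembly and Gauss quadrature.
"""

import numpy as np
import pytest

from hiveweave.fixtures import make_fixture
from hiveweave.geometry_core import GeometryError, mesh_volume
from hiveweave.is_pipeline import (Attractor, LoadCase, VoxelField,
                                   apply_attractors, is_generate,
                                   simp_optimize, summarize_load_case,
                                   voxels_to_hexcells)
from hiveweave.vo_pipeline import HiveSpec

E0, EMIN, NU = 1.0, 1e-9, 0.3


def _symbolic_quad_ke(nu=NU):
    """Plane-stress stiffness of the unit bilinear quad, exact integrals."""
    import sympy as sp
    x, y = sp.symbols("x y")
    N = [(1 - x) * (1 - y), x * (1 - y), x * y, (1 - x) * y]
    D = sp.Rational(1) / (1 - nu ** 2) * sp.Matrix(
        [[1, nu, 0], [nu, 1, 0], [0, 0, sp.Rational(1 - nu, 2)]])
    B = sp.zeros(3, 8)
    for a in range(4):
        B[0, 2 * a] = sp.diff(N[a], x)
        B[1, 2 * a + 1] = sp.diff(N[a], y)
        B[2, 2 * a] = sp.diff(N[a], y)
        B[2, 2 * a + 1] = sp.diff(N[a], x)
    KE = sp.integrate(sp.integrate(B.T * D * B, (x, 0, 1)), (y, 0, 1))
    return np.array(KE.evalf(), dtype=float)


def reference_oc_simp(nx, ny, case, iterations):
    """Textbook OC loop: dense assembly, explicit element loops."""
    KE = _symbolic_quad_ke()
    nid = lambda ix, iy: ix * (ny + 1) + iy
    ndof = 2 * (nx + 1) * (ny + 1)
    corners = [(0, 0), (1, 0), (1, 1), (0, 1)]

    def edof(ex, ey):
        dofs = []
        for cx, cy in corners:
            n = nid(ex + cx, ey + cy)
            dofs += [2 * n, 2 * n + 1]
        return dofs

    F = np.zeros(ndof)
    for (vx, vy), (dx, dy), kgf in case.loads:
        f = np.array([dx, dy]) / np.hypot(dx, dy) * kgf * 9.81 / 4
        for cx, cy in corners:
            n = nid(vx + cx, vy + cy)
            F[2 * n] += f[0]
            F[2 * n + 1] += f[1]
    fixed = set()
    for vx, vy in case.supports:
        fixed.update(edof(vx, vy))
    free = np.array([d for d in range(ndof) if d not in fixed])

    centers = [(ex + 0.5, ey + 0.5) for ex in range(nx) for ey in range(ny)]
    x = np.full(nx * ny, case.volume_fraction)
    p, rmin, f_target = case.penalization, case.filter_radius, case.volume_fraction
    eid = lambda ex, ey: ex * ny + ey

    for _ in range(iterations):
        K = np.zeros((ndof, ndof))
        for ex in range(nx):
            for ey in range(ny):
                dofs = edof(ex, ey)
                e = EMIN + x[eid(ex, ey)] ** p * (E0 - EMIN)
                for a in range(8):
                    for b in range(8):
                        K[dofs[a], dofs[b]] += e * KE[a, b]
        U = np.zeros(ndof)
        U[free] = np.linalg.solve(K[np.ix_(free, free)], F[free])
        dc = np.zeros(nx * ny)
        for ex in range(nx):
            for ey in range(ny):
                ue = U[edof(ex, ey)]
                ce = ue @ KE @ ue
                i = eid(ex, ey)
                dc[i] = -p * x[i] ** (p - 1) * (E0 - EMIN) * ce
        # sensitivity filter, explicit double loop
        dcf = np.zeros_like(dc)
        for i, ci in enumerate(centers):
            tot, acc = 0.0, 0.0
            for j, cj in enumerate(centers):
                w = rmin - np.hypot(ci[0] - cj[0], ci[1] - cj[1])
                if w > 0:
                    tot += w
                    acc += w * x[j] * dc[j]
            dcf[i] = acc / (tot * max(1e-3, x[i]))
        l1, l2, move = 0.0, 1e9, 0.2
        while (l2 - l1) / (l1 + l2 + 1e-30) > 1e-10:
            lmid = (l1 + l2) / 2
            xnew = np.clip(x * np.sqrt(np.maximum(-dcf, 0) / lmid),
                           np.maximum(0, x - move), np.minimum(1, x + move))
            if xnew.mean() - f_target > 0:
                l1 = lmid
            else:
                l2 = lmid
        x = xnew
    return x.reshape((nx, ny))  # element (ex, ey)


class TestSimpOptimize:
    def test_saturated_volume_fraction_all_solid(self):
        case = LoadCase([((1, 0), (0, -1), 1.0)], [(0, 0)], volume_fraction=1.0)
        field, _ = simp_optimize((2, 1), case, iterations=3)
        assert np.allclose(field.rho, 1.0)

    def test_two_element_series_bar_splits_evenly(self):
        # two bar elements in series: compliance 1/rho1^p + 1/rho2^p under
        # rho1 + rho2 = 1 is symmetric, so the OC iteration's fixed point
        # shares material equally (closed-form oracle)
        from hiveweave.is_pipeline import _oc_update

        def dc(x, p):
            return -p / x ** (p + 1)   # d/drho of sum(1/rho^p)

        # (0.5, 0.5) is a fixed point of the update ...
        even = np.array([0.5, 0.5])
        assert _oc_update(even, dc(even, 3.0), np.ones(2), f=0.5) == \
            pytest.approx([0.5, 0.5], abs=1e-6)
        # ... and from any start the iterates stay symmetric about it
        # with the volume constraint met exactly at every step
        x = np.array([0.8, 0.2])
        for _ in range(50):
            x = _oc_update(x, dc(x, 3.0), np.ones(2), f=0.5)
            assert x.mean() == pytest.approx(0.5, abs=1e-9)
            assert abs(x[0] - 0.5) == pytest.approx(abs(x[1] - 0.5), abs=1e-9)
        # with the linear (p=1) interpolation the iteration converges to the
        # even split as soon as the move limit allows
        y = np.array([0.8, 0.2])
        for _ in range(2):
            y = _oc_update(y, dc(y, 1.0), np.ones(2), f=0.5)
        assert y == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_cantilever_matches_reference_oc(self):
        case = make_fixture("loadcase", {"shape": "cantilever",
                                         "nx": 8, "ny": 5})
        field, _ = simp_optimize((8, 5), case, iterations=30)
        expected = reference_oc_simp(8, 5, case, iterations=30)
        assert np.abs(field.rho - expected).max() < 1e-6

    def test_volume_fraction_exact_every_iteration(self):
        case = make_fixture("loadcase", {"shape": "cantilever"})
        means = []
        simp_optimize((8, 5), case, iterations=10,
                      callback=lambda it, x, c: means.append(x.mean()))
        assert all(abs(m - 0.4) < 1e-3 for m in means)

    def test_compliance_decreases(self):
        case = make_fixture("loadcase", {"shape": "cantilever"})
        _, hist = simp_optimize((8, 5), case, iterations=20)
        assert np.all(np.isfinite(hist))
        assert hist[-1] < hist[0]

    def test_symmetric_problem_symmetric_field(self):
        case = LoadCase(
            loads=[((3, 4), (0, -1), 40.0), ((4, 4), (0, -1), 40.0)],
            supports=[(0, 0), (7, 0)], volume_fraction=0.4)
        field, _ = simp_optimize((8, 5), case, iterations=20)
        assert np.abs(field.rho - field.rho[::-1, :]).max() < 1e-9

    def test_mesh_independence_smoke(self):
        # doubling resolution (filter radius scaled along, load distributed
        # over the free edge) moves final compliance by less than 10%;
        # run at a resolution where Q4 discretization error in bending is
        # subdominant
        def edge_cantilever(nx, ny, rmin):
            return LoadCase(
                loads=[((nx - 1, j), (0, -1), 10.0 / ny) for j in range(ny)],
                supports=[(0, j) for j in range(ny)],
                volume_fraction=0.4, filter_radius=rmin)
        _, hc = simp_optimize((64, 40), edge_cantilever(64, 40, 4.0),
                              iterations=30)
        _, hf = simp_optimize((128, 80), edge_cantilever(128, 80, 8.0),
                              iterations=30)
        assert abs(hf[-1] - hc[-1]) / hc[-1] < 0.10

    def test_invalid_case_rejected(self):
        with pytest.raises(GeometryError, match="load and one support"):
            LoadCase([], [(0, 0)], volume_fraction=0.4)
        with pytest.raises(GeometryError, match="volume fraction"):
            LoadCase([((0, 0), (0, -1), 1.0)], [(0, 0)], volume_fraction=1.5)


class TestSummarizeLoadCase:
    def test_colony_floor_totals_design_load(self):
        case = make_fixture("loadcase", {"shape": "colony-floor", "load": 80.0})
        assert summarize_load_case(case) == pytest.approx(80.0)

    def test_two_halves_sum(self):
        case = LoadCase([((0, 0), (0, -1), 40.0), ((1, 0), (0, -1), 40.0)],
                        [(0, 0)], volume_fraction=0.5)
        assert summarize_load_case(case) == pytest.approx(80.0)


class TestApplyAttractors:
    def test_empty_list_is_identity(self):
        f = VoxelField.uniform((4, 4, 3), 10.0, 0.3)
        g = apply_attractors(f, [])
        assert np.array_equal(g.rho, f.rho)

    def test_tight_falloff_boosts_single_voxel(self):
        f = VoxelField.uniform((4, 4, 1), 10.0, 0.2)
        # falloff under half a voxel edge: kernel support stays inside it
        att = Attractor("point", (15.0, 15.0, 5.0), strength=0.5, falloff=4.0)
        g = apply_attractors(f, [att])
        assert np.sum(g.rho > 0.2 + 1e-12) == 1
        assert g.rho[1, 1, 0] == pytest.approx(0.7)

    def test_monotone_non_increasing_with_distance(self):
        f = VoxelField.uniform((6, 6, 4), 10.0, 0.3)
        att = Attractor("point", (30.0, 30.0, 20.0), strength=0.5,
                        falloff=40.0)
        g = apply_attractors(f, [att])
        d = att.distance(f.centers())
        rho = g.rho.ravel(order="F")
        order = np.argsort(d)
        assert np.all(np.diff(rho[order]) <= 1e-12)

    def test_line_attractor_and_clamping(self):
        f = VoxelField.uniform((5, 5, 2), 10.0, 0.9)
        att = Attractor("line", ((0, 25, 10), (50, 25, 10)), strength=0.8,
                        falloff=30.0)
        g = apply_attractors(f, [att])
        assert g.rho.max() <= 1.0


class TestVoxelsToHexcells:
    def test_all_below_threshold_empty(self):
        f = VoxelField.uniform((4, 4, 2), 10.0, 0.2)
        grids = voxels_to_hexcells(f, 0.5)
        assert [len(g) for g in grids] == [0, 0]

    def test_all_above_threshold_full(self):
        f = VoxelField.uniform((4, 5, 2), 10.0, 0.9)
        grids = voxels_to_hexcells(f, 0.5)
        assert [len(g) for g in grids] == [20, 20]

    def test_random_field_counts_match_threshold(self):
        rng = np.random.default_rng(3)
        rho = rng.random((5, 6, 4))
        f = VoxelField((5, 6, 4), 10.0, rho)
        grids = voxels_to_hexcells(f, 0.5)
        for k, g in enumerate(grids):
            assert len(g) == int(np.sum(rho[:, :, k] >= 0.5))

    def test_threshold_bounds(self):
        f = VoxelField.uniform((2, 2, 1), 10.0, 0.5)
        with pytest.raises(GeometryError):
            voxels_to_hexcells(f, 1.0)


class TestIsGenerate:
    @pytest.fixture(scope="class")
    def small_spec(self):
        return HiveSpec(8.0, 30.0, 40.0, landing_platform=None)

    @pytest.fixture(scope="class")
    def small_case(self):
        return make_fixture("loadcase", {"shape": "colony-floor",
                                         "dims": (10, 10, 8), "load": 80.0})

    def test_enclosed_cavity_volume(self, small_spec, small_case):
        m = is_generate(small_spec, small_case, "enclosed", dims=(10, 10, 8),
                        iterations=4)
        assert mesh_volume(m.cavity_mesh) == pytest.approx(8.0, rel=0.05)
        assert m.meta["total_load_kgf"] == pytest.approx(80.0)

    def test_open_variant_reaches_top(self, small_spec, small_case):
        m = is_generate(small_spec, small_case, "open", dims=(10, 10, 8),
                        iterations=3)
        # the recess pierces the top boundary of the domain
        top = m.cavity_mesh.vertices[:, 2].max()
        assert top >= m.enclosure_mesh.vertices[:, 2].max() - 1e-6

    def test_layers_weavable_and_continuous(self, small_spec, small_case):
        from hiveweave.weaving import continuity_check
        m = is_generate(small_spec, small_case, "enclosed", dims=(10, 10, 8),
                        iterations=3)
        woven = [tp for pat in m.layers for tp in pat.toolpaths]
        assert woven
        assert all(continuity_check(tp).continuous for tp in woven)
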