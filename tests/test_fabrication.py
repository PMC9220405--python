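"""Module splitting, shrinkage compensation, G-code emission."""

import numpy as np
import pytest

from hiveweave.fabrication import (MachineProfile, ShrinkageModel,
                                   apply_shrinkage, compensate_shrinkage,
                                   estimate_material, parse_gcode_paths,
                                   slice_into_modules, to_gcode)
from hiveweave.geometry_core import GeometryError
from hiveweave.hexgrid import radial_grid
from hiveweave.vo_pipeline import (ScaffoldModel, SlicePattern, generate_hive)
from hiveweave.weaving import Toolpath, path_length, weave


@pytest.fixture(scope="module")
def demo_model():
    from hiveweave.vo_pipeline import HiveSpec, OffsetSchedule
    spec = HiveSpec(30.0, 50.0, 60.0, channel_diameter=18.0)
    sched = OffsetSchedule(((3.0, "wall"), (20.0, "weave"),
                            (18.0, "channel"), (3.0, "wall")))
    machine = MachineProfile(max_print_diameter=70.0, filament_diameter=2.85)
    return generate_hive(spec, sched, machine, s=8.0), machine


def toy_model(n_layers=10, layer_h=2.0):
    from hiveweave.geometry_core import SolidMesh
    layers = []
    for i in range(n_layers):
        tp = weave(radial_grid(1, 5.0), z=i * layer_h, layer=i)
        layers.append(SlicePattern(z=i * layer_h, layer=i, rings=[],
                                   toolpaths=[tp], channel_cells=[]))
    mesh = SolidMesh.box((40, 40, n_layers * layer_h),
                         center=(0, 0, n_layers * layer_h / 2))
    return ScaffoldModel(layers, mesh, mesh, {}, layer_h)


class TestSliceIntoModules:
    def test_ceiling_division_count(self):
        # 100 cm total at a 15 cm limit -> 7 modules
        model = toy_model(n_layers=500, layer_h=2.0)
        mods = slice_into_modules(model, MachineProfile())
        assert len(mods) == 7

    def test_single_module_at_limit(self):
        model = toy_model(n_layers=75, layer_h=2.0)   # exactly 15 cm
        mods = slice_into_modules(model, MachineProfile())
        assert len(mods) == 1

    def test_partition_is_exact(self, demo_model):
        model, machine = demo_model
        mods = slice_into_modules(model, machine)
        z0, z1 = model.z_extent
        assert mods[0].z0 == z0 and mods[-1].z1 == z1
        for a, b in zip(mods, mods[1:]):
            assert a.z1 == b.z0
        assert sum(len(m.layers) for m in mods) == len(model.layers)

    def test_limits_respected(self, demo_model):
        model, machine = demo_model
        for m in slice_into_modules(model, machine):
            assert (m.z1 - m.z0) / 10 <= machine.max_module_height + 1e-9
            assert m.diameter <= machine.max_print_diameter + 1e-9

    def test_oversized_layer_names_layer(self):
        model = toy_model()
        tiny = MachineProfile(max_print_diameter=0.5)
        with pytest.raises(GeometryError, match="layer"):
            slice_into_modules(model, tiny)


class TestShrinkage:
    def test_zero_factor_identity(self):
        model = toy_model()
        out = compensate_shrinkage(model, ShrinkageModel.isotropic(0.0))
        assert np.allclose(out.cavity_mesh.vertices, model.cavity_mesh.vertices)

    def test_twenty_percent_linear_gains(self):
        model = toy_model()
        comp = compensate_shrinkage(model, ShrinkageModel.isotropic(0.2))
        ratio = comp.cavity_mesh.vertices.max() / model.cavity_mesh.vertices.max()
        assert ratio == pytest.approx(1.25)
        vol_ratio = (comp.cavity_volume() / model.cavity_volume())
        assert vol_ratio == pytest.approx(1.25 ** 3)   # 1.953125

    def test_round_trip_volume_error_under_0p1_percent(self, demo_model):
        model, _ = demo_model
        sh = ShrinkageModel.isotropic(0.2)
        back = apply_shrinkage(compensate_shrinkage(model, sh), sh)
        err = abs(back.cavity_volume() - model.cavity_volume()) / \
            model.cavity_volume()
        assert err < 1e-3

    def test_factor_half_rejected(self):
        with pytest.raises(GeometryError):
            ShrinkageModel.isotropic(0.5)


class TestToGcode:
    @pytest.fixture
    def machine(self):
        return MachineProfile(bead_width=2.0, layer_height=1.0,
                              filament_diameter=2.85)

    def test_square_loop_four_extruding_moves(self, machine):
        from hiveweave.fabrication import RingModule
        tp = Toolpath.from_polyline(
            np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float), closed=True)
        pat = SlicePattern(z=0.0, layer=0, rings=[], toolpaths=[tp],
                           channel_cells=[])
        mod = RingModule(0, 0.0, 1.0, [pat], 2.0)
        text = to_gcode([mod], machine)[0]
        g1 = [l for l in text.splitlines() if l.startswith("G1 ")]
        g0 = [l for l in text.splitlines() if l.startswith("G0 ")]
        assert len(g1) == 4 and len(g0) == 1

    def test_extrusion_register_volumetric_formula(self, machine):
        from hiveweave.fabrication import RingModule
        tp = Toolpath.from_polyline(np.array([[0, 0], [100, 0]], float),
                                    closed=False)
        pat = SlicePattern(z=0.0, layer=0, rings=[], toolpaths=[tp],
                           channel_cells=[])
        text = to_gcode([RingModule(0, 0.0, 1.0, [pat], 2.0)], machine)[0]
        e = float([l for l in text.splitlines()
                   if l.startswith("G1")][-1].split("E")[1])
        expected = 100 * (2.0 * 1.0) / (np.pi * (2.85 / 2) ** 2)
        assert e == pytest.approx(expected, abs=1e-4)   # ~31.35 mm

    def test_reparse_recovers_vertices(self, machine):
        tp = weave(radial_grid(1, 5.0))
        from hiveweave.fabrication import RingModule
        pat = SlicePattern(z=0.0, layer=0, rings=[], toolpaths=[tp],
                           channel_cells=[])
        text = to_gcode([RingModule(0, 0.0, 2.0, [pat], 2.0)], machine)[0]
        paths = parse_gcode_paths(text)
        assert len(paths) == 1
        assert np.abs(paths[0] - tp.vertices).max() <= 0.05 + 1e-9

    def test_discontinuous_path_refused(self, machine):
        from hiveweave.fabrication import RingModule
        tp = weave(radial_grid(0, 5.0))
        ext = tp.extrude.copy()
        ext[1] = False
        bad = Toolpath(tp.segments, ext)
        pat = SlicePattern(z=0.0, layer=0, rings=[], toolpaths=[bad],
                           channel_cells=[])
        with pytest.raises(GeometryError, match="discontinuous"):
            to_gcode([RingModule(0, 0.0, 2.0, [pat], 2.0)], machine)

    def test_empty_module_rejected(self, machine):
        from hiveweave.fabrication import RingModule
        with pytest.raises(GeometryError, match="no toolpaths"):
            to_gcode([RingModule(0, 0.0, 2.0, [], 0.0)], machine)

    def test_extrusion_register_strictly_increasing(self, demo_model):
        model, machine = demo_model
        mods = slice_into_modules(model, machine)
        text = to_gcode(mods[:1], machine)[0]
        es = [float(l.split("E")[1]) for l in text.splitlines()
              if l.startswith("G1 ") and "E" in l]
        assert all(b > a for a, b in zip(es, es[1:]))


class TestEstimateMaterial:
    def test_arithmetic(self):
        from hiveweave.fabrication import RingModule
        tp = Toolpath.from_polyline(np.array([[0, 0], [1000, 0]], float),
                                    closed=False)
        pat = SlicePattern(z=0.0, layer=0, rings=[], toolpaths=[tp],
                           channel_cells=[])
        machine = MachineProfile(bead_width=2.0, layer_height=1.0)
        est = estimate_material([RingModule(0, 0, 1, [pat], 1.0)], machine,
                                density=1.3)
        assert est["bead_volume_cm3"] == pytest.approx(2.0)
        assert est["mass_g"] == pytest.approx(2.6)

    def test_zero_modules_zero_totals(self):
        est = estimate_material([], MachineProfile(), density=1.3)
        assert est["mass_g"] == 0.0

    def test_mass_additive_in_layers(self):
        m1 = toy_model(n_layers=5)
        m2 = toy_model(n_layers=10)
        machine = MachineProfile()
        e1 = estimate_material(slice_into_modules(m1, machine), machine)
        e2 = estimate_material(slice_into_modules(m2, machine), machine)
        assert e2["mass_g"] == pytest.approx(2 * e1["mass_g"])
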