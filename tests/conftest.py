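import numpy as np
import pytest

from hiveweave.fabrication import MachineProfile
from hiveweave.geometry_core import PlanarRegion
from hiveweave.vo_pipeline import HiveSpec, OffsetSchedule


@pytest.fixture
def square10():
    """Axis-aligned square of side 10 mm."""
    return PlanarRegion(np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float))


@pytest.fixture
def circle64():
    """Regular 64-gon approximating a circle of radius 5 mm."""
    return PlanarRegion.circle(5.0, segments=64)


@pytest.fixture
def demo_spec():
    return HiveSpec(cavity_target_volume=30.0, cavity_height=50.0,
                    entrance_diameter=60.0, channel_diameter=18.0)


@pytest.fixture
def demo_schedule():
    return OffsetSchedule(((3.0, "wall"), (20.0, "weave"),
                           (18.0, "channel"), (3.0, "wall")))


@pytest.fixture
def fdm_machine():
    return MachineProfile(max_print_diameter=70.0, max_module_height=15.0,
                          bead_width=3.0, layer_height=2.0,
                          filament_diameter=2.85)
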