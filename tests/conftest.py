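import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from irisopt.geometry import VoxelGrid, make_sphere_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def unit_grid(half_extent: float, spacing: float = 1.0) -> VoxelGrid:
    """Isotropic grid centered on the origin spanning +/- half_extent mm."""
    lo = np.array([-half_extent] * 3)
    return VoxelGrid.for_extent(lo, -lo, spacing)


@pytest.fixture
def sphere10():
    """Digitized ball of radius 10 mm on a 1 mm grid, labeled GTV."""
    return make_sphere_phantom(unit_grid(12.0), (0, 0, 0), 10.0, label="GTV")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
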