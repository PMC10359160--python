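import numpy as np
import pytest

from planct.phantom import PhantomSpec, make_phantom
from planct.volumes import ScalarVolume, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def desk_grid_48():
    return VolumeGrid((48, 48, 48), (2.5, 2.5, 2.5))


@pytest.fixture(scope="session")
def phantom_case_48():
    """One deterministic desk-scale phantom pair, shared across tests."""
    spec = PhantomSpec(grid=VolumeGrid((48, 48, 48), (2.5, 2.5, 2.5)), seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def phantom_case_96():
    """One full-size phantom pair (96^3 at 2.5 mm)."""
    return make_phantom(PhantomSpec(seed=3))


def random_volume(grid: VolumeGrid, rng, lo=-1000.0, hi=1000.0) -> ScalarVolume:
    return ScalarVolume(grid, rng.uniform(lo, hi, grid.shape))
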