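import numpy as np
import pytest

from voxdose90 import CompartmentSet, PhantomSpec, ScalarVolume, VoxelGrid, make_phantom


@pytest.fixture(scope="session")
def default_truth():
    """Default phantom: ~1.7 L liver, one 30 mm-radius tumor, T/N 3.75."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_truth():
    """Small, fast phantom on a 5 mm grid for structural tests."""
    return make_phantom(PhantomSpec(grid_spacing_mm=(5.0, 5.0, 5.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_dose_volume(rng, shape=(12, 10, 8), spacing=(4.0, 4.0, 4.0)):
    grid = VoxelGrid(shape=shape, spacing_mm=spacing)
    values = rng.gamma(2.0, 30.0, size=shape)
    return ScalarVolume(grid, values, "dose_Gy")


def single_compartment(grid):
    return CompartmentSet(grid, {"roi": np.ones(grid.shape, bool)})
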