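import numpy as np
import pytest

from svatlas.data_model import DisplacementField, ScalarVolume, TissueProbMap, VoxelGrid
from svatlas.synth import GrowthModel, default_grid, make_icosphere, make_phantom


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0), (-15.0, -15.0, -15.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere4():
    return make_icosphere(4, 1.0)


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3, 1.0)


@pytest.fixture(scope="session")
def phantom12():
    """One folded phantom at 12 months on the desk-scale grid (no noise)."""
    return make_phantom(
        12.0, GrowthModel(noise_sd=0.0), default_grid(48, 2.0), seed=5
    )


def smooth_field(grid: VoxelGrid, max_mm: float, seed: int) -> DisplacementField:
    """Small smooth random field for algebra tests (not boundary-tapered)."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed).normal(size=grid.shape + (3,))
    for c in range(3):
        r[..., c] = gaussian_filter(r[..., c], 2.0)
    mag = np.linalg.norm(r, axis=-1).max()
    return DisplacementField(grid, r * (max_mm / mag))
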