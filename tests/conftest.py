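import numpy as np
import pytest

from synct.core import CTVolume, Grid, StructureMask
from synct.phantom import PhantomConfig, simulate_pair


DESK_GRID = dict(grid_shape=(64, 64, 32), spacing=(2.5, 2.5, 3.0))


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(noise_sigma=0.0, enhancement_jitter_hu=0.0,
                         n_samples=8, seed=7, **DESK_GRID)


@pytest.fixture(scope="session")
def noiseless_sample(noiseless_config):
    return simulate_pair(noiseless_config, 0)


@pytest.fixture(scope="session")
def default_sample():
    """One phantom at the default study conditions on a desk-size grid."""
    cfg = PhantomConfig(n_samples=2, seed=3, **DESK_GRID)
    return simulate_pair(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape=(10, 10, 8), spacing=(1.0, 1.5, 2.0), p=0.3,
                name="m"):
    grid = Grid(shape, spacing)
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return StructureMask(name, m, grid)


def ball_mask(shape, spacing, center_vox, radius_mm, name="ball"):
    grid = Grid(shape, spacing)
    ax = grid.voxel_centers()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = [ax[i][center_vox[i]] for i in range(3)]
    m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius_mm ** 2
    return StructureMask(name, m, grid)
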