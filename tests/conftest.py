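import numpy as np
import pytest

from jetsr.fixtures import make_fixtures, patch_grid, small_jet_geometry
from jetsr.pipeline import generate_patches, stream_frames


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_frames():
    """Two simulated frames of the compressed jet geometry."""
    geom = small_jet_geometry(n_frames=8)
    return list(stream_frames(geom, patch_grid(), seed=3, frames=[3, 5]))


@pytest.fixture(scope="session")
def small_pairs(small_frames):
    """Patch pairs sampled from one small frame."""
    from jetsr.patches import sample_patches

    fp = small_frames[0]
    rng = np.random.default_rng(42)
    return sample_patches(fp.lr, fp.hr_velocity, fp.hr_mask, rng)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
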