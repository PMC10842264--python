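import numpy as np
import pytest

from voxmatch import VoxelGrid, make_helix_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20451)


@pytest.fixture
def random_grid(rng):
    """A small random positive grid at the tomographic pixel size."""
    return VoxelGrid(rng.random((12, 10, 11)), 2.612, origin=(1.0, -2.0, 3.0))


@pytest.fixture
def bundle():
    """A deterministic 3-helix bundle, the canonical synthetic target."""
    return make_helix_bundle(3, 30, 10.0, seed=7, model_id="bundle")
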