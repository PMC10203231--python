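import numpy as np
import pytest

from cvrkit import (
    breath_hold_paradigm,
    draw_ground_truth,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_atlas():
    """4-parcel phantom on an 8x8x6 grid (384 voxels, all labelled)."""
    return generate_phantom(n_parcels=4, grid_shape=(8, 8, 6), seed=1)


@pytest.fixture(scope="session")
def bh_paradigm():
    return breath_hold_paradigm(tr=2.0)


@pytest.fixture
def truth_factory(small_atlas):
    def make(n_subjects=1, **kw):
        kw.setdefault("seed", 1)
        return draw_ground_truth(small_atlas, n_subjects, **kw)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
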