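import numpy as np
import pytest

from tractmsa.synthetic_cohort import generate_atlas, generate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    """3-tract atlas on an 8x8x8 grid with a 2-tract RoB pool."""
    return generate_atlas(grid_shape=(8, 8, 8), n_tracts=3, seed=1, radius=1.6, n_pool=2)


@pytest.fixture(scope="session")
def cohort():
    """A 40-patient fully-complete synthetic cohort, low noise.

    Lesions are drawn large (median 300 voxels) so per-tract damage
    spans a good part of [0, 1] and the predictor-backed coalition game
    is non-trivial at the binary corners.
    """
    return generate_cohort(n_patients=40, seed=11, noise_sd=0.05, size_dist=(300, 0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
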