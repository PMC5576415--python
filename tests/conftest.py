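import numpy as np
import pytest

from adwave.features import build_feature_matrix
from adwave.synthetic import PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def edge_image():
    """Diagonal step edge — the worst case for critically sampled DWTs."""
    n = 128
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (ii + jj < n).astype(float)


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 20-subject cohort at reduced resolution (128px, 8 slices,
    level-3 subbands are 16x16 so the per-slice feature count is still 1536)."""
    spec = PhantomSpec(image_size=128, n_slices=8, effect_size=1.0,
                       noise_sd=0.02, seed=11)
    stacks, labels = generate_cohort(spec, 10, 10)
    return stacks, labels


@pytest.fixture(scope="session")
def small_features(small_cohort):
    stacks, _ = small_cohort
    return build_feature_matrix(stacks, transform="dtcwt", scale=3)
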