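import numpy as np
import pytest

from segae.phantom import make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless exact-mixture phantom: 48^3, C=3, M=4 (CSF, GM, WM, WMH)."""
    truth, volumes = make_phantom(
        (48, 48, 48), channels=3, n_materials=4, lesion_fraction=0.05, seed=1
    )
    return truth, volumes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16, 16), density=0.03, blobs=3):
    """Sparse-ish random binary mask with a few clusters."""
    mask = rng.random(shape) < density
    for _ in range(blobs):
        c = rng.integers(2, np.array(shape) - 2)
        mask[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = True
    return mask
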