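import numpy as np
import pytest

from outlierloss import figure9_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def figure9():
    """The five-region 100x100 test image and its region annotations."""
    mask, regions = figure9_image()
    return mask, regions


def random_masks(rng, n, shape=(20, 20), p=0.3):
    """n random binary masks with foreground probability p."""
    return [(rng.random(shape) < p).astype(np.int64) for _ in range(n)]
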