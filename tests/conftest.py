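import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_blobs(rng: np.random.Generator, shape=(48, 48), sigma=2.0, thresh=0.05):
    """Smooth-noise thresholded blob pattern, for filter/skeleton tests."""
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma) > thresh
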