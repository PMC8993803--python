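import numpy as np
import pytest

from mammowave.image_core import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.random((16, 16)))
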