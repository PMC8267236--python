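import numpy as np
import pytest

from aanet.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A 32-pixel phantom spec: fast, still divisible by 16 for the network."""
    return PhantomSpec(image_size=32, noise_sd=0.05, seed=7)
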