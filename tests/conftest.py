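import numpy as np
import pytest

from weibullcv import WeibullParams, sample_weibull


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_small_samples(rng):
    """A pair of size-10 unit-exponential samples (shape 1, scale 0.5)."""
    params = WeibullParams(0.5, 1.0)
    return sample_weibull(10, params, rng), sample_weibull(10, params, rng)
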