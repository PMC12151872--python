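import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_wls_instance(rng):
    """One random 8-point weighted-regression instance with unequal weights."""
    x = rng.normal(size=8)
    y = 1.5 + 2.0 * x + rng.normal(scale=0.7, size=8)
    w = rng.uniform(0.2, 3.0, size=8)
    return x, y, w
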