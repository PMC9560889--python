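import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_signal(rng):
    """1750-sample z-scored Gaussian noise at fs=250 (one 7 s segment)."""
    x = rng.standard_normal(1750)
    return (x - x.mean()) / x.std()


def zscore(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std()


@pytest.fixture
def zscored():
    return zscore
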