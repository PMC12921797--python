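import numpy as np
import pytest

from ddnet.montage import CHANNELS_40, standard_montage
from ddnet.preprocess import CANONICAL_BANDS


@pytest.fixture(scope="session")
def montage40():
    return standard_montage()


@pytest.fixture(scope="session")
def montage10():
    return standard_montage(CHANNELS_40[:10])


@pytest.fixture(scope="session")
def theta():
    return CANONICAL_BANDS[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_weighted_graph(rng, n, density=0.7):
    """Random symmetric nonnegative test matrix with zero diagonal."""
    w = rng.uniform(0.1, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w
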