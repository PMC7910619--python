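import numpy as np
import pytest

from ptgen import make_grid
from ptgen.model import Hyperparams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hyper():
    return Hyperparams()


@pytest.fixture
def square5():
    return make_grid([5, 5])


@pytest.fixture
def grid3():
    return make_grid([3, 3])
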