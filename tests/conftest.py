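import numpy as np
import pytest

from glitimer import ReadoutModel
from glitimer.scenarios import make_preset


@pytest.fixture(scope="session")
def readout():
    return ReadoutModel(eta=1.0)


@pytest.fixture(scope="session")
def wt_config():
    return make_preset("WT")


@pytest.fixture(scope="session")
def direct_config():
    return make_preset("direct")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
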