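import numpy as np
import pytest

from replinet import hdg, rps


@pytest.fixture(scope="session")
def RPS():
    return rps()


@pytest.fixture(scope="session")
def HDG():
    return hdg()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251002)
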