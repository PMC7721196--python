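import numpy as np
import pytest

from dualloop import canonical_parameters, find_limit_cycle
from dualloop.sensitivity import CycleSensitivity


@pytest.fixture(scope="session")
def params():
    return canonical_parameters()


@pytest.fixture(scope="session")
def lc(params):
    cycle = find_limit_cycle(params)
    assert cycle is not None
    return cycle


@pytest.fixture(scope="session")
def analysis(params, lc):
    a = CycleSensitivity(params, lc=lc)
    a._compute()
    return a


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
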