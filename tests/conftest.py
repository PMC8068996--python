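import numpy as np
import pytest

import acnsim as a


@pytest.fixture(scope="session")
def small_domain():
    return a.WorkingDomain(64, 64)


@pytest.fixture(scope="session")
def network(small_domain):
    """A reproducible 4-end-point network on a 64x64 domain."""
    return a.build_network(small_domain, 4, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


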