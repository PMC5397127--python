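import numpy as np
import pytest

from mtvbm.phantom import (
    DEFAULT_PROTOCOLS,
    PhantomSpec,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Jitter-free 48-cube phantom with the default tissue table."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_volumes(default_phantom):
    """Noiseless three-contrast simulation of the default phantom."""
    return {
        name: simulate_acquisition(default_phantom.fields, proto)
        for name, proto in DEFAULT_PROTOCOLS.items()
    }


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(PhantomSpec.small())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
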