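import numpy as np
import pytest

from murivess import phantom as ph


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64-cubed phantom shared across tests."""
    return ph.generate_phantom(ph.PhantomConfig(shape=(64, 64, 64), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
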