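import numpy as np
import pytest

from mesomig.simulator import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_config():
    """Reduced-grid configuration shared by the heavier integration tests."""
    return RunConfig.reduced()
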