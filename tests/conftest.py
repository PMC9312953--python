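import numpy as np
import pytest

from becg.corpus import reduced_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_run():
    """One shared demonstration-scale training run for every test that needs
    a trained codec (several minutes; executed at most once per session)."""
    return reduced_protocol(seed=123)
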