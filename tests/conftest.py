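import numpy as np
import pytest
from hypothesis import settings

from egfrbench import get_q_spec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def europe_spec():
    return get_q_spec("europe")


@pytest.fixture(scope="session")
def us_spec():
    return get_q_spec("us")


@pytest.fixture
def rng():
    return np.random.default_rng(20240828)
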