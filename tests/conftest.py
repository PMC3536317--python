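import numpy as np
import pytest

from bcdyn import DEFAULT_ESTROGEN_PARAMS, TABLE1_PARAMS
from bcdyn.synthetic import sample_parameter_set


@pytest.fixture(scope="session")
def table1():
    return TABLE1_PARAMS


@pytest.fixture(scope="session")
def estro():
    return DEFAULT_ESTROGEN_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def draw_params(model, seed):
    """Random valid parameter set from the default +/-20% ranges."""
    return sample_parameter_set(model=model, seed=seed)
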