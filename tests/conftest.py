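import numpy as np
import pytest

from metacomm import ModelParams, initial_condition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    return ModelParams(r=0.3, K=10.0, alpha=0.1, lam=0.4, S=3, P=12)


@pytest.fixture
def random_field(small_params, rng):
    return initial_condition(small_params, rng)
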