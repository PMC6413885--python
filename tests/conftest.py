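import numpy as np
import pytest

from stencen.params import ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def sten(params):
    return params.sten


@pytest.fixture
def cen(params):
    return params.cen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
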