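import math

import numpy as np
import pytest

from wc2d.model_core import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20221219)


@pytest.fixture
def fc_params():
    """Fully-connected critical parameter set of the reference protocol."""
    return ModelParams(L=1, lam=math.inf, alpha_rate=0.1, beta_gain=1.0,
                       w00=0.1, ws0=13.8, h=1e-8)


@pytest.fixture
def d2_params():
    """2D critical parameter set (L=100 analytic grid, lambda=1)."""
    return ModelParams(L=100, lam=1.0, alpha_rate=0.1, beta_gain=1.0,
                       w00=0.1, ws0=13.8, h=1e-8)
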