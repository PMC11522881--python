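import numpy as np
import pytest

from settleopt import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def mid_params():
    """Central sweep probabilities with moderate shocks."""
    return ModelParams(
        p_s_save=0.5,
        p_h_build=0.5,
        p_l_move=0.5,
        p_s_loss=0.25,
        p_force_move=0.25,
        payoff_scenario="additive",
    )
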