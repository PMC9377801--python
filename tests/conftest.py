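import dataclasses

import pytest
from hypothesis import settings

from premo import PremoParams, make_clamp_design

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_params():
    return PremoParams()


@pytest.fixture
def saturated_clamp_params():
    """Regime of the continuous-report clamp experiment: saturated 5 deg
    proprioceptive shift, w_p = 0.25 (variance ratio 3), visual shift off."""
    return dataclasses.replace(
        PremoParams(), w_p=0.25, beta_p_sat=5.0, beta_v_sat=0.0, K=0.2
    )


@pytest.fixture
def clamp15_schedule():
    return make_clamp_design(0, 300, 15.0, 0)
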