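import numpy as np
import pytest

from laryngosim.bcm_core import (MuscleActivation, SimulationConfig,
                                 activation_to_params, simulate_vocal_folds,
                                 steady_state_segment)
from laryngosim.controller import ControllerGains, DelayConfig
from laryngosim.forward_map import GridSpec, build_forward_map
from laryngosim.paradigms import TABLE4_CASES


@pytest.fixture(scope="session")
def fmap():
    """Reduced operating-region forward-map slice at P_s = 800 Pa."""
    return build_forward_map(GridSpec.test_grid())


@pytest.fixture(scope="session")
def fine_map():
    """Full-range 800-Pa slice at the 0.02 coarse activation step."""
    return build_forward_map(GridSpec(a_ct_step=0.02, a_ta_step=0.02,
                                      ps_values=(800.0,)))


@pytest.fixture(scope="session")
def case_segments():
    """Steady-state waveform segments of the four iso-f_o cases at 800 Pa."""
    segs = {}
    for name, (ct, ta) in TABLE4_CASES.items():
        p = activation_to_params(MuscleActivation(ct, ta, 0.5))
        w = simulate_vocal_folds(p, SimulationConfig(P_s=800.0, duration=1.0))
        segs[name] = steady_state_segment(w, 0.25)
    return segs


@pytest.fixture()
def delays():
    return DelayConfig()


@pytest.fixture()
def unity_gains():
    return ControllerGains(g_fb_aud=1.0, lambda_ff=0.0)
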