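import numpy as np
import pytest

import spindlesee as sp


@pytest.fixture(scope="session")
def ideal_params():
    """Linear two-spring MTU: no stiffening, damping, relaxation or noise.

    With k_lin = k_tendon = 1 N/mm the closed forms are trivial:
    x_fas = L/2, RFD = 0.5, k_MTU = 0.5, k_FAS = 1.
    """
    return sp.GeneratorParams(k_lin=1.0, k_quad=0.0, c_damp=0.0,
                              k_tendon=1.0, k_see=1.0, k_relax=0.0,
                              tau_relax=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def default_params():
    return sp.GeneratorParams()


@pytest.fixture(scope="session")
def ramp_trial_ctrl(default_params):
    return sp.generate_trial(sp.ramp_hold(), default_params, "CTRL", seed=11)


@pytest.fixture(scope="session")
def ramp_conditioned(ramp_trial_ctrl):
    return sp.condition_channels(ramp_trial_ctrl)


@pytest.fixture(scope="session")
def triangle_conditioned(default_params):
    rec = sp.generate_trial(sp.triangle(), default_params, "CTRL", seed=11)
    return sp.condition_channels(rec)


@pytest.fixture(scope="session")
def sinusoid_conditioned(default_params):
    rec = sp.generate_trial(sp.sinusoid(), default_params, "CTRL", seed=11)
    return sp.condition_channels(rec)


def make_linear_trial(k_fas=1.0, k_series=1.0, condition="CTRL",
                      protocol=None, seed=0):
    """Noise-free linear-spring trial for analytic recovery checks."""
    protocol = protocol or sp.ramp_hold()
    # condition selects the series combination; choose k_tendon/k_see so the
    # effective series stiffness equals k_series in that condition
    if condition == "CTRL":
        params = sp.GeneratorParams(k_lin=k_fas, k_quad=0.0, c_damp=0.0,
                                    k_tendon=k_series, k_relax=0.0,
                                    tau_relax=0.0, noise_sd=0.0)
    else:
        params = sp.GeneratorParams(k_lin=k_fas, k_quad=0.0, c_damp=0.0,
                                    k_tendon=2.0 * k_series,
                                    k_see=2.0 * k_series, k_relax=0.0,
                                    tau_relax=0.0, noise_sd=0.0)
    return sp.generate_trial(protocol, params, condition, seed=seed)
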