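import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    from nihsim import KineticParameters
    return KineticParameters()


@pytest.fixture
def capacity(params):
    from nihsim import LayerCapacity
    return LayerCapacity.from_volumes(1e-8, 1e-8, params)


@pytest.fixture
def graft_tree():
    from nihsim import make_graft
    return make_graft("femoropopliteal")


@pytest.fixture
def smooth_wave():
    from nihsim import smooth_waveform, synth_doppler
    return smooth_waveform(synth_doppler(seed=42), window=11)


@pytest.fixture
def graft_network():
    from nihsim.synthetic_data import fixture_network
    return fixture_network("femoropopliteal")


def euler_wall_oracle(state0, wss, params, cap, days, dt=1e-3):
    """Independent fixed-step explicit-Euler integration of the wall ODE."""
    from nihsim.biochemistry import shear_dependent_rates, wall_rhs
    rates = shear_dependent_rates(wss, params)
    y = state0.as_array()
    n = int(round(days / dt))
    for _ in range(n):
        y = y + dt * wall_rhs(y, rates, params, cap)
    return y


@pytest.fixture
def euler_oracle():
    return euler_wall_oracle
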