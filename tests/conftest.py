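import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def tait_params():
    from cellshock import eos

    return eos.StateEquationParams(family="tait", A0=450.0, p0=101.325,
                                   kappa=1.5, alpha3=0.8)


@pytest.fixture
def exp_params():
    from cellshock import eos

    return eos.StateEquationParams(family="exponential", A0=300.0, p0=100.0,
                                   B0=1.0, Bprime=-0.25)
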