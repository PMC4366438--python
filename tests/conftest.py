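import pytest
from hypothesis import HealthCheck, settings

import strs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def heroin_traj():
    sc = strs.named_scenario("heroin")
    return strs.integrate(sc.params, sc.init, (0.0, sc.horizon))


@pytest.fixture(scope="session")
def fig4_traj():
    sc = strs.named_scenario("fig4")
    return strs.integrate_pulsed(sc.params, sc.pulses, sc.init, (0.0, 100.0))


@pytest.fixture(scope="session")
def fig5_traj():
    sc = strs.named_scenario("fig5")
    return strs.integrate_pulsed(sc.params, sc.pulses, sc.init, (0.0, 500.0))
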