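import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regcycle.model import ConnectionMask, SystemInputs, default_parameters

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def full_mask():
    return ConnectionMask.full()


@pytest.fixture(scope="session")
def stress_inputs():
    return SystemInputs(stress=0.5, mtor_total=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def network_fixture():
    from regcycle.synth import FixtureSpec, generate_network_fixture

    return generate_network_fixture(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def regime_results(params):
    """The full 12-row qualitative regime suite, run once per session."""
    from regcycle.scenarios import run_regime_suite

    return run_regime_suite(params, seed=0)


@pytest.fixture(scope="session")
def stress_sweep(params):
    """Full-model stress sweep used for the oscillation-window checks."""
    from regcycle.bifurcation import sweep
    from regcycle.model import ConnectionMask

    return sweep(params, ConnectionMask.full(), "stress",
                 np.linspace(0.0, 30.0, 81), seed=0)
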