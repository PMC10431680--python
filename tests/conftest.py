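import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

from sigbcircuit import (
    ParameterSet,
    SimulationSettings,
    StressProtocol,
    build_core_network,
    build_modified_network,
)


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def core_network(default_params):
    return build_core_network(default_params)


@pytest.fixture(scope="session")
def modified_network():
    return build_modified_network(ParameterSet(eta_amp=0.05, eta_freq=1.0))


@pytest.fixture(scope="session")
def short_protocol():
    """Cheap protocol for engine tests that do not need the full 200 h."""
    return StressProtocol(t_burnin_start=-2.0, t_stress=0.0, t_end=20.0)


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
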