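import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from chaosnet import NeuronParameters
    return NeuronParameters()


@pytest.fixture(scope="session")
def default_record(default_params):
    """One 10 s recording of the reference neuron, shared across tests."""
    from chaosnet import integrate
    return integrate(default_params, t_transient=5000.0, t_record=10000.0)
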