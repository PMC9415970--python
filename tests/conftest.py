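import numpy as np
import pytest

from breathalert.simulator import (
    DEFAULT_FIELD_PARAMS,
    deap_protocol,
    field_protocol,
    simulate_bivariate,
    simulate_trace,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def field_trace():
    """One simulated field-protocol subject (sit/walk/run/sit at 12 Hz)."""
    return simulate_trace(field_protocol(), DEFAULT_FIELD_PARAMS, seed=11)


@pytest.fixture(scope="session")
def deap_trace():
    """One simulated two-channel literature-style recording (63 s at 128 Hz)."""
    return simulate_bivariate(deap_protocol(), seed=21)
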