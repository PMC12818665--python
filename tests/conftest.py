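import numpy as np
import pytest

from cytotriad import CytokineState, DEFAULT_INITIAL_STATE, ParameterSet


@pytest.fixture
def params() -> ParameterSet:
    """Reference parameter set."""
    return ParameterSet()


@pytest.fixture
def initial_state() -> CytokineState:
    return CytokineState(0.0, *DEFAULT_INITIAL_STATE)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
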