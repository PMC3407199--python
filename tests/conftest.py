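import numpy as np
import pytest

from idpnmr import (
    DEFAULT_CONTEXT,
    PeptideSequence,
    SimulationConfig,
    TC5B_SEQUENCE,
    make_constants,
)


@pytest.fixture(scope="session")
def tc5b() -> PeptideSequence:
    return PeptideSequence(TC5B_SEQUENCE)


@pytest.fixture(scope="session")
def constants():
    """Interaction constants at the 60.25 MHz 15N field, rNH = 1.02 A, CSA 172 ppm."""
    return make_constants(DEFAULT_CONTEXT)


@pytest.fixture()
def cfg() -> SimulationConfig:
    return SimulationConfig(seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
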