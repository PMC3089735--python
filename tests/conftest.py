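import numpy as np
import pytest

from nirsbp import pipeline as pl
from nirsbp import synthgen as sg


@pytest.fixture(scope="session")
def default_session():
    """One fully simulated session with the default configuration."""
    return sg.simulate_session(sg.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_bundle(default_session):
    """Analysis results of the default simulated session."""
    s = default_session
    return pl.analyze_session(s.nirs, s.pressure, s.schedule, pl.AnalysisParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
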