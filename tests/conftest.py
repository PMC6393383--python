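import numpy as np
import pytest

from tanpause.dynamics import (
    ModelParams,
    ScenarioContext,
    StimulusProtocol,
    detect_pause,
    integrate,
)

HORIZON_MS = 4000.0


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def block_stim():
    """The 300 ms block protocol used throughout the figures."""
    return StimulusProtocol([(0.0, 300.0)], HORIZON_MS)


@pytest.fixture(scope="session")
def pulse_train():
    """50 Hz x 10 pulse calibration protocol."""
    return StimulusProtocol([(20.0 * k, 20.0 * k + 10.0) for k in range(10)],
                            HORIZON_MS)


@pytest.fixture(scope="session")
def tp_by_rpe(params, block_stim):
    """Pause duration for rpe in {-1, 0, 1} at defaults (shared, expensive)."""
    out = {}
    for rpe in (-1.0, 0.0, 1.0):
        trace = integrate(params, block_stim, ScenarioContext(rpe=rpe))
        out[rpe] = detect_pause(trace).duration_ms
    return out
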