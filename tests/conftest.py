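import numpy as np
import pytest

from slipsynergy import synthetic
from slipsynergy.io_model import CANONICAL_CHANNELS, EmgTrial, PipelineConfig


@pytest.fixture(scope="session")
def ground_truth():
    """Five planted modes, 10% envelope noise, fixed seed."""
    return synthetic.make_ground_truth(k=5, template="fig4_like", seed=1)


@pytest.fixture(scope="session")
def small_session(ground_truth):
    """One participant's full 10-trial session with its scripts and truth."""
    session, w_by_stage, scripts = synthetic.make_session(ground_truth, "P01", seed=3)
    return session, w_by_stage, scripts


@pytest.fixture()
def config():
    return PipelineConfig()


def make_emg(signal, rate_hz=600.0, trial_id="t"):
    """8-channel EmgTrial from a signal array (rows broadcast to 8)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = np.tile(signal, (8, 1))
    return EmgTrial(trial_id, "other", CANONICAL_CHANNELS, signal, rate_hz)
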