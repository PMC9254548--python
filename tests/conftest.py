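import numpy as np
import pytest

from smrbci.containers import EEGRecording
from smrbci.montage import EEG_CHANNELS, EOG_CHANNELS
from smrbci.orchestrator import analyze_session
from smrbci.synthetic import SimulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate=512.0, labels=None):
    labels = labels or (EEG_CHANNELS + EOG_CHANNELS)[: data.shape[1]]
    return EEGRecording(np.asarray(data, dtype=float), rate, labels)


@pytest.fixture(scope="session")
def short_config():
    """Reduced session size for fast unit tests (not the study defaults)."""
    return SimulationConfig(seed=7, trials_per_class=5,
                            trial_duration=(3.0, 3.5),
                            inter_trial=(1.0, 1.5))


@pytest.fixture(scope="session")
def short_session(short_config):
    return simulate_session(short_config, 1)


@pytest.fixture(scope="session")
def short_analysis(short_session):
    rec, trials, _truth = short_session
    return analyze_session(rec, trials, hop=0.25)


@pytest.fixture(scope="session")
def labelled_frame(short_analysis):
    return short_analysis["frame"]


def random_spd(rng, n, scale=1.0, cond=10.0):
    """Random SPD matrix with eigenvalues spread over ~cond."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eigs = scale * np.exp(rng.uniform(0, np.log(cond), n))
    return (q * eigs) @ q.T
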