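import numpy as np
import pytest

from anesdepth import io as aio
from anesdepth import synthetic
from anesdepth.core import AnesthesiaState, Epoch
from anesdepth.features import extract_features


def make_epoch(samples, fs_hz=128.0, label=AnesthesiaState.AWAKE):
    return Epoch(samples=np.asarray(samples, float), fs_hz=fs_hz, label=label)


def tone_epoch(freq_hz, fs_hz=128.0, duration_s=4.0, amplitude=10.0, phase=0.0):
    t = np.arange(int(duration_s * fs_hz)) / fs_hz
    return make_epoch(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs_hz)


def noise_epoch(rng, fs_hz=128.0, duration_s=4.0, amplitude=10.0):
    return make_epoch(amplitude * rng.standard_normal(int(duration_s * fs_hz)), fs_hz)


@pytest.fixture(scope="session")
def default_study_features():
    """Feature matrix of the default synthetic study (seed 0).

    Session-scoped: the study replica is the shared substrate for the
    classifier, GA and acceptance tests.
    """
    rec = synthetic.simulate_study(synthetic.SimConfig(seed=0))
    epochs = aio.epochize(rec, epoch_s=2.0, overlap=0.5)
    epochs = aio.reject_artifacts(epochs)
    return extract_features(epochs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
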