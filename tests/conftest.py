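import numpy as np
import pytest

from chirpinv.pipeline import RunConfig, stimulus_windows
from chirpinv.stimulus import BeatSpec, ChirpSpec, make_waveform_set


@pytest.fixture(scope="session")
def waves():
    """The canonical 8-waveform chirp-on-beat set (defaults)."""
    return make_waveform_set()


@pytest.fixture(scope="session")
def stim_windows(waves):
    """30 ms chirp-window samples per waveform label."""
    return stimulus_windows(waves)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def beat_spec():
    return BeatSpec()


@pytest.fixture(scope="session")
def chirp_spec():
    return ChirpSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
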