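import numpy as np
import pytest

from chirpff.audio_io import TARGET_RATE, AudioSignal
from chirpff import features, synthetic

RATE = TARGET_RATE


@pytest.fixture(scope="session")
def tone_1khz():
    t = np.arange(RATE) / RATE
    return AudioSignal(np.sin(2 * np.pi * 1000 * t), RATE, source_id="tone1k")


@pytest.fixture(scope="session")
def toy_segments():
    """Twenty labelled 10-s segments (10 per class) from the generator."""
    return synthetic.make_segment_dataset(10, seed=1)


@pytest.fixture(scope="session")
def toy_features(toy_segments):
    return [features.mfcc(s) for s in toy_segments]
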