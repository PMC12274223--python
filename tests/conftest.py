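import numpy as np
import pytest

from atas import DetectionConfig, UtteranceSpec, make_synthetic_utterance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return DetectionConfig()


@pytest.fixture
def five_burst_utterance():
    """5 voiced 600-ms tone bursts separated by 4 silences of 300 ms, clean."""
    intervals = []
    for i in range(5):
        intervals.append(("voiced", 600.0))
        if i < 4:
            intervals.append(("silent", 300.0))
    spec = UtteranceSpec(intervals=tuple(intervals), voiced_amplitude=0.8,
                         sample_rate=16000, seed=7)
    return make_synthetic_utterance(spec)
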