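import numpy as np
import pytest

from melcrnn.io import Recording
from melcrnn.labeling import LabelScheme, PerclosTrace
from melcrnn.model import ModelConfig
from melcrnn.spectral import SpectralConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spectral():
    """Small transform keeping feature maps cheap: 16-point STFT, hop 4."""
    return SpectralConfig(n_fft=16, hop=4, n_mels=5, rate=400.0)


@pytest.fixture
def tiny_model_cfg():
    """A miniature CRNN for fast forward/backward tests."""
    return ModelConfig(in_channels=2, conv_widths=(4, 6, 8), rnn_hidden=8,
                       fc_size=8, n_classes=2)


@pytest.fixture
def small_recording(rng):
    """Three-channel, 2 s recording at 400 Hz."""
    data = rng.standard_normal((3, 800))
    return Recording(data=data, rate=400.0, channel_names=("C1", "C2", "C3"))


@pytest.fixture
def flat_trace():
    times = np.arange(40.0)
    return PerclosTrace(times=times, values=np.full(40, 0.1))


@pytest.fixture
def two_class():
    return LabelScheme(mode="two_class")


@pytest.fixture
def three_class():
    return LabelScheme(mode="three_class")
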