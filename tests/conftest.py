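import numpy as np
import pytest

from mosaicspeech import AudioSignal, zwicker_band_edges
from mosaicspeech.synthetic import generate_pseudo_speech, japanese_profile


@pytest.fixture(scope="session")
def bands20():
    """The 20-band critical-band analysis range, 50-6400 Hz."""
    return zwicker_band_edges(50, 6400)


@pytest.fixture(scope="session")
def speech_1s():
    """One pseudo-sentence of 8 units (~1 s at 44.1 kHz), fixed seed."""
    sig, annot = generate_pseudo_speech(japanese_profile(), 8, seed=20240101)
    return sig, annot


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def white_signal(rng, n=44100, fs=44100.0, amp=0.1):
    return AudioSignal(rng.standard_normal(n) * amp, fs)
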