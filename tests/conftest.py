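import numpy as np
import pytest

from choruscope import AudioSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory for pure sinusoids: tone(freq_hz, seconds, rate, amp)."""
    def _make(freq, seconds=1.0, rate=44100.0, amp=0.5, phase=0.0):
        t = np.arange(int(round(seconds * rate))) / rate
        return AudioSignal(amp * np.sin(2 * np.pi * freq * t + phase), rate)
    return _make


@pytest.fixture
def bin_centred_tone(tone):
    """A tone landing exactly on STFT bin k for win_len 512 at 44.1 kHz."""
    def _make(k=86, seconds=2.0, rate=44100.0, win_len=512):
        return tone(k * rate / win_len, seconds, rate)
    return _make
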