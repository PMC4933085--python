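"""Audio I/O, preprocessing and time-frequency representations.

Everything downstream (acoustic indices, sparse approximation, latent
component analysis) consumes the containers defined here: a mono
:class:`AudioSignal`, a non-negative :class:`Spectrogram` (linear-STFT or
constant-Q flavour), the Hilbert amplitude :class:`Envelope` and the
time-averaged :class:`SpectrumProfile`.

Conventions
-----------
* Samples live in [-1, 1]; 16-bit PCM is scaled by 1/32768.
* Stereo is mixed down to mono by the arithmetic mean of the channels.
* STFT frames are 0-based, a frame's timestamp is the centre of its
  window, and a trailing partial window is dropped.
* dBFS is referenced to a full-scale amplitude of 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.io.wavfile
import scipy.signal
import scipy.sparse

from .exceptions import InputError, ParameterError

__all__ = [
    "AudioSignal",
    "Spectrogram",
    "Envelope",
    "SpectrumProfile",
    "read_audio",
    "write_audio",
    "highpass_filter",
    "stft_spectrogram",
    "constant_q_spectrogram",
    "amplitude_envelope",
    "mean_spectrum",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Real-valued samples, nominally in [-1, 1].
    rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError("AudioSignal requires a 1-D (mono) sample array")
        if self.samples.size < 1:
            raise InputError("AudioSignal requires at least one sample")
        if not self.rate > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Spectrogram:
    """Non-negative time-frequency magnitude matrix with axis metadata.

    ``values`` has shape ``(len(freqs), len(times))``; ``scale`` is
    ``"linear"`` for STFT bins or ``"log"`` for constant-Q bins.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("Spectrogram values must be a 2-D matrix")
        if self.values.shape != (self.freqs.size, self.times.size):
            raise InputError(
                f"shape mismatch: values {self.values.shape} vs axes "
                f"({self.freqs.size}, {self.times.size})"
            )
        if np.any(self.values < 0):
            raise InputError("Spectrogram values must be non-negative")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise InputError("frequency axis must be strictly increasing")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("time axis must be strictly increasing")
        if self.scale not in ("linear", "log"):
            raise ParameterError(f"unknown scale {self.scale!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_csv(self, path) -> None:
        """Export as CSV: header row of frame times, first column of bin
        frequencies, magnitude cells in between."""
        with open(path, "w") as fh:
            fh.write("freq_hz," + ",".join(f"{t:.6f}" for t in self.times) + "\n")
            for f, row in zip(self.freqs, self.values):
                fh.write(f"{f:.6f}," + ",".join(repr(v) for v in row) + "\n")


@dataclass
class Envelope:
    """Non-negative amplitude envelope sampled at ``rate`` Hz."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise InputError("Envelope values must be non-negative")


@dataclass
class SpectrumProfile:
    """Per-bin mean magnitude over time (the 'mean spectrum')."""

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.power.shape != self.freqs.shape:
            raise InputError("power and freqs must have the same length")
        if np.any(self.power < 0):
            raise InputError("SpectrumProfile power must be non-negative")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,  # scipy loads 24-bit PCM into int32
}


def read_audio(path) -> AudioSignal:
    """Read a RIFF WAV file (8/16/24/32-bit PCM or IEEE float) as a mono
    :class:`AudioSignal` with samples scaled to [-1, 1].

    Stereo files are mixed down by the arithmetic mean of the channels.
    """
    try:
        rate, data = scipy.io.wavfile.read(path)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read WAV file: {path}") from exc
    except ValueError as exc:
        raise InputError(f"unreadable or corrupt WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"zero-length audio in {path}")
    if data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        x = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:  # float32 / float64 WAV
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioSignal(x, float(rate))


def write_audio(path, sig: AudioSignal) -> None:
    """Write a 16-bit PCM mono WAV file (samples clipped to [-1, 1])."""
    x = np.clip(sig.samples, -1.0, 1.0)
    scipy.io.wavfile.write(path, int(sig.rate), (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def highpass_filter(sig: AudioSignal, cutoff_hz: float = 500.0,
                    slope_db_per_octave: int = 12) -> AudioSignal:
    """Zero-phase Butterworth high-pass filter.

    ``slope_db_per_octave`` of 12 or 24 selects a 2nd- or 4th-order
    design, applied forward-backward (``sosfiltfilt``) for zero phase.
    Note the two passes square the magnitude response, so the effective
    level at the cutoff is -6 dB (or -12 dB for the 4th-order design).
    """
    if not 0 < cutoff_hz < sig.rate / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sig.rate / 2} Hz)")
    if slope_db_per_octave not in (12, 24):
        raise ParameterError("slope must be 12 or 24 dB/octave")
    order = slope_db_per_octave // 6
    sos = scipy.signal.butter(order, cutoff_hz, btype="highpass",
                              fs=sig.rate, output="sos")
    return AudioSignal(scipy.signal.sosfiltfilt(sos, sig.samples), sig.rate)


# ---------------------------------------------------------------------------
# time-frequency transforms
# ---------------------------------------------------------------------------

def _get_window(window, win_len: int) -> np.ndarray:
    if isinstance(window, str):
        name = {"rectangular": "boxcar"}.get(window, window)
        return scipy.signal.get_window(name, win_len, fftbins=True)
    w = np.asarray(window, dtype=np.float64)
    if w.shape != (win_len,):
        raise ParameterError("window array length must equal win_len")
    return w


def _frame_starts(n_samples: int, win_len: int, hop: int) -> np.ndarray:
    if n_samples < win_len:
        raise InputError(
            f"signal of {n_samples} samples is shorter than one window "
            f"({win_len} samples)")
    n_frames = (n_samples - win_len) // hop + 1
    return np.arange(n_frames) * hop


def stft_spectrogram(sig: AudioSignal, win_len: int = 512, hop: int = 256,
                     window_fn="hann") -> Spectrogram:
    """Magnitude short-time Fourier spectrogram.

    Frequencies are ``k * rate / win_len`` for ``k = 0 .. win_len//2``;
    frame times are window centres; the last partial window is dropped.
    """
    if win_len < 2:
        raise ParameterError("win_len must be >= 2")
    if hop < 1:
        raise ParameterError("hop must be >= 1")
    w = _get_window(window_fn, win_len)
    starts = _frame_starts(sig.samples.size, win_len, hop)
    frames = np.lib.stride_tricks.sliding_window_view(sig.samples, win_len)[::hop]
    mags = np.abs(np.fft.rfft(frames * w, axis=1)).T  # (bins, frames)
    freqs = np.fft.rfftfreq(win_len, d=1.0 / sig.rate)
    times = (starts + win_len / 2.0) / sig.rate
    return Spectrogram(mags, freqs, times, scale="linear")


def _cq_frequencies(fmin: float, bins_per_octave: int, n_bins: int) -> np.ndarray:
    b = np.arange(n_bins)
    # split the exponent so that bins an octave apart differ by an exact
    # float multiplication by 2 (freqs[b + bpo] == 2 * freqs[b] exactly)
    return fmin * (2.0 ** (b // bins_per_octave)) * \
        (2.0 ** ((b % bins_per_octave) / bins_per_octave))


def constant_q_spectrogram(sig: AudioSignal, fmin: float = 110.0,
                           bins_per_octave: int = 24, hop: int = 1024,
                           n_bins: int | None = None) -> Spectrogram:
    """Constant-Q (log-frequency) magnitude spectrogram.

    Each bin ``b`` is a matched filter: a Hann-windowed complex sinusoid
    at ``fmin * 2**(b / bins_per_octave)`` whose length keeps the ratio
    of centre frequency to bandwidth (Q) constant. Filters are applied
    in the frequency domain (FFT-kernel method); kernel responses are
    normalised so a unit-amplitude tone at a bin centre reads ~1.
    """
    if fmin <= 0:
        raise ParameterError("fmin must be positive")
    if bins_per_octave < 1:
        raise ParameterError("bins_per_octave must be >= 1")
    nyq = sig.rate / 2.0
    if fmin >= nyq:
        raise ParameterError("fmin must be below Nyquist")
    if n_bins is None:
        n_bins = int(math.floor(bins_per_octave * math.log2(nyq / fmin)))
        n_bins = max(n_bins, 1)
    elif fmin * 2.0 ** (n_bins / bins_per_octave) > nyq:
        raise ParameterError(
            f"top constant-Q bin exceeds Nyquist ({nyq} Hz); reduce n_bins")
    freqs = _cq_frequencies(fmin, bins_per_octave, n_bins)

    q = 1.0 / (2.0 ** (1.0 / bins_per_octave) - 1.0)
    n0 = int(math.ceil(q * sig.rate / fmin))
    fft_len = 1 << max(int(math.ceil(math.log2(n0))), 1)
    if sig.samples.size < fft_len:
        raise InputError(
            f"signal too short for constant-Q analysis: needs >= {fft_len} "
            f"samples at fmin={fmin} Hz, got {sig.samples.size}")

    # sparse spectral kernels, positive-frequency half only
    rows, cols, vals = [], [], []
    n_rbins = fft_len // 2 + 1
    for b, fc in enumerate(freqs):
        n_k = min(int(math.ceil(q * sig.rate / fc)), fft_len)
        w = scipy.signal.get_window("hann", n_k, fftbins=False)
        kern = np.zeros(fft_len, dtype=np.complex128)
        start = (fft_len - n_k) // 2
        t = np.arange(n_k)
        kern[start:start + n_k] = w * np.exp(2j * np.pi * fc * t / sig.rate)
        spec = np.fft.fft(kern)[:n_rbins] / (w.sum() / 2.0)
        keep = np.abs(spec) >= 0.005 * np.abs(spec).max()
        idx = np.nonzero(keep)[0]
        rows.extend([b] * idx.size)
        cols.extend(idx.tolist())
        vals.extend(np.conj(spec[idx]).tolist())
    kmat = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_bins, n_rbins), dtype=np.complex128)

    starts = _frame_starts(sig.samples.size, fft_len, hop)
    frames = np.lib.stride_tricks.sliding_window_view(sig.samples, fft_len)[::hop]
    mags = np.empty((n_bins, starts.size))
    chunk = max(1, int(2 ** 22 // fft_len))  # bound FFT workspace memory
    for i in range(0, starts.size, chunk):
        spec = np.fft.rfft(frames[i:i + chunk], axis=1)
        mags[:, i:i + chunk] = np.abs(kmat @ spec.T) / fft_len
    times = (starts + fft_len / 2.0) / sig.rate
    return Spectrogram(mags, freqs, times, scale="log")


def amplitude_envelope(sig: AudioSignal) -> Envelope:
    """Hilbert amplitude envelope: modulus of the analytic signal."""
    if sig.samples.size < 1:
        raise InputError("empty signal")
    return Envelope(np.abs(scipy.signal.hilbert(sig.samples)), sig.rate)


def mean_spectrum(spec: Spectrogram) -> SpectrumProfile:
    """Per-bin mean magnitude across time frames."""
    if spec.values.size == 0:
        raise InputError("empty spectrogram")
    return SpectrumProfile(spec.values.mean(axis=1), spec.freqs)
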