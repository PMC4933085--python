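"""Community-level acoustic indices.

Implements the six indices routinely used to summarise soundscape
recordings — NDSI, acoustic entropy H (= sh x th), ADI, AEI, ACI and the
Bioacoustic Index — together with their building blocks (Shannon
entropy, Gini coefficient, band occupancy proportions).

All entropies use the natural logarithm with the 0*ln(0) := 0
convention; sh and th are normalised by ln(R) so they (and their
product H) lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .audio_spectra import (
    AudioSignal, Envelope, Spectrogram, SpectrumProfile,
    amplitude_envelope, highpass_filter, mean_spectrum, stft_spectrogram,
)
from .exceptions import InputError, ParameterError, UndefinedInputError

__all__ = [
    "BandSplit", "IndexConfig", "IndexReport",
    "shannon_entropy", "gini",
    "spectral_entropy", "temporal_entropy", "acoustic_entropy",
    "ndsi", "band_proportions", "adi", "aei", "aci",
    "bioacoustic_index", "compute_index_report",
]


@dataclass(frozen=True)
class BandSplit:
    """Frequency bands (Hz) contrasting anthropophony and biophony."""

    anthro_lo: float = 200.0
    anthro_hi: float = 2000.0
    bio_lo: float = 2000.0
    bio_hi: float = 8000.0

    def __post_init__(self) -> None:
        if not (self.anthro_lo < self.anthro_hi <= self.bio_lo < self.bio_hi):
            raise ParameterError("bands must satisfy "
                                 "anthro_lo < anthro_hi <= bio_lo < bio_hi")


@dataclass(frozen=True)
class IndexConfig:
    """Shared preprocessing and per-index parameters for a report run."""

    win_len: int = 512
    hop: int = 256
    window: str = "hann"
    highpass_hz: Optional[float] = None      # e.g. 500.0 to mimic field preprocessing
    highpass_slope: int = 12
    bands: BandSplit = field(default_factory=BandSplit)
    adi_bands: int = 10
    adi_threshold_db: float = -50.0
    aci_clump_seconds: Optional[float] = 5.0  # None = whole signal in one clump
    bi_lo: float = 2000.0
    bi_hi: float = 8000.0

    def as_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class IndexReport:
    """Per-recording values of the six indices plus their sub-terms.

    Indices whose input was degenerate (e.g. silence) are NaN, with the
    reason recorded in ``errors``.
    """

    ndsi: float
    adi: float
    aei: float
    sh: float
    th: float
    h: float
    aci: float
    bi: float
    parameters: dict
    errors: dict

    COLUMNS = ("ndsi", "adi", "aei", "sh", "th", "h", "aci", "bi")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.COLUMNS}


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def shannon_entropy(p, normalized: bool = False) -> float:
    """Shannon entropy H' = -sum(p_i ln p_i) of non-negative weights.

    Weights are normalised to a probability distribution first. With
    ``normalized=True`` the result is divided by ln(R) so the maximum
    (uniform) case maps to 1; for R = 1 the normalised entropy is 0 by
    convention.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise InputError("expected a non-empty 1-D weight vector")
    if np.any(p < 0):
        raise InputError("weights must be non-negative")
    total = p.sum()
    if total <= 0:
        raise UndefinedInputError("entropy undefined for an all-zero vector")
    q = p / total
    nz = q[q > 0]
    h = float(-(nz * np.log(nz)).sum())
    if normalized:
        if p.size == 1:
            return 0.0
        h /= np.log(p.size)
    return h


def gini(p) -> float:
    """Gini coefficient G = sum_ij |p_i - p_j| / (2 n sum(p)).

    0 for perfectly even weights, approaching 1 - 1/n when all mass is
    concentrated on a single category.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise InputError("expected a non-empty 1-D weight vector")
    if np.any(p < 0):
        raise InputError("weights must be non-negative")
    total = p.sum()
    if total <= 0:
        raise UndefinedInputError("Gini undefined for an all-zero vector")
    n = p.size
    x = np.sort(p)
    # sorted identity: sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) x_(i)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))


# ---------------------------------------------------------------------------
# entropy indices
# ---------------------------------------------------------------------------

def spectral_entropy(prof: SpectrumProfile) -> float:
    """Normalised Shannon entropy of the mean spectrum (sh in [0, 1])."""
    if prof.power.sum() <= 0:
        raise UndefinedInputError("spectral entropy undefined: silent spectrum")
    return shannon_entropy(prof.power, normalized=True)


def temporal_entropy(env: Envelope) -> float:
    """Normalised Shannon entropy of the amplitude envelope (th in [0, 1])."""
    if env.values.sum() <= 0:
        raise UndefinedInputError("temporal entropy undefined: silent envelope")
    return shannon_entropy(env.values, normalized=True)


def acoustic_entropy(sig: AudioSignal, win_len: int = 512, hop: int = 256,
                     window: str = "hann") -> tuple[float, float, float]:
    """Acoustic entropy H = sh * th.

    sh is the normalised entropy of the mean STFT magnitude spectrum,
    th the normalised entropy of the Hilbert amplitude envelope. H is 0
    for a pure tone and approaches 1 for sustained broadband sound.
    """
    spec = stft_spectrogram(sig, win_len=win_len, hop=hop, window_fn=window)
    sh = spectral_entropy(mean_spectrum(spec))
    th = temporal_entropy(amplitude_envelope(sig))
    return sh, th, sh * th


# ---------------------------------------------------------------------------
# band-energy indices
# ---------------------------------------------------------------------------

def _band_power(power: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs < hi)
    return float(power[mask].sum())


def ndsi(sig: AudioSignal, bands: BandSplit = BandSplit(),
         win_len: int = 512, hop: int = 256, window: str = "hann") -> float:
    """Normalized Difference Soundscape Index.

    (biophony - anthropophony) / (biophony + anthropophony), computed
    from the mean STFT power spectrum (Welch-style average). Result in
    [-1, 1]: +1 when all in-band energy is biophony (2-8 kHz default).
    """
    if bands.bio_hi > sig.rate / 2:
        raise ParameterError("biophony band extends beyond Nyquist")
    spec = stft_spectrogram(sig, win_len=win_len, hop=hop, window_fn=window)
    power = (spec.values ** 2).mean(axis=1)
    return _ndsi_from_power(power, spec.freqs, bands)


def _ndsi_from_power(power: np.ndarray, freqs: np.ndarray, bands: BandSplit) -> float:
    a = _band_power(power, freqs, bands.anthro_lo, bands.anthro_hi)
    b = _band_power(power, freqs, bands.bio_lo, bands.bio_hi)
    if a + b <= 0:
        raise UndefinedInputError("NDSI undefined: no power in either band")
    return (b - a) / (b + a)


def band_proportions(spec: Spectrogram, n_bands: int = 10,
                     threshold_dbfs: float = -50.0) -> np.ndarray:
    """Occupancy distribution over equal-width frequency bands.

    The spectrogram is split into ``n_bands`` contiguous bands; in each,
    the proportion of time-frequency cells whose level exceeds
    ``threshold_dbfs`` (dB relative to the loudest cell) is counted, and
    the proportions are renormalised to sum to 1.
    """
    if spec.freqs.size < n_bands:
        raise ParameterError(
            f"spectrogram has {spec.freqs.size} rows; needs >= {n_bands}")
    vmax = spec.values.max()
    if vmax <= 0:
        raise UndefinedInputError("occupancy undefined: silent spectrogram")
    floor = vmax * 10.0 ** (threshold_dbfs / 20.0)
    props = np.array([
        np.mean(band > floor) for band in np.array_split(spec.values, n_bands, axis=0)
    ])
    total = props.sum()
    if total <= 0:
        raise UndefinedInputError("no cell above threshold in any band")
    return props / total


def adi(spec: Spectrogram, n_bands: int = 10, threshold_dbfs: float = -50.0) -> float:
    """Acoustic Diversity Index: unnormalised Shannon entropy of the
    band occupancy distribution; range [0, ln(n_bands)]."""
    return shannon_entropy(band_proportions(spec, n_bands, threshold_dbfs),
                           normalized=False)


def aei(spec: Spectrogram, n_bands: int = 10, threshold_dbfs: float = -50.0) -> float:
    """Acoustic Evenness Index: Gini coefficient of band occupancy;
    0 = perfectly even, -> 1 - 1/n_bands for single-band concentration."""
    return gini(band_proportions(spec, n_bands, threshold_dbfs))


def aci(spec: Spectrogram, clump_seconds: Optional[float] = 5.0) -> float:
    """Acoustic Complexity Index.

    Per frequency row and per temporal clump:
    sum_t |I(f,t+1) - I(f,t)| / sum_t I(f,t), summed over rows and
    clumps. Invariant to global amplitude scaling; a row with zero
    energy inside a clump contributes 0.
    """
    v = spec.values
    if v.shape[1] < 2:
        raise InputError("ACI needs at least 2 frames")
    if clump_seconds is None:
        bounds = [0, v.shape[1]]
    else:
        if spec.times.size > 1:
            frame_dt = float(np.median(np.diff(spec.times)))
        else:
            frame_dt = clump_seconds
        per = max(int(round(clump_seconds / frame_dt)), 2)
        bounds = list(range(0, v.shape[1], per)) + [v.shape[1]]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 2:
            continue  # clumps need >= 2 frames for a difference
        block = v[:, lo:hi]
        d = np.abs(np.diff(block, axis=1)).sum(axis=1)
        s = block.sum(axis=1)
        nz = s > 0
        total += float((d[nz] / s[nz]).sum())
    return total


def bioacoustic_index(sig: AudioSignal, lo: float = 2000.0, hi: float = 8000.0,
                      win_len: int = 512, hop: int = 256,
                      window: str = "hann") -> float:
    """Bioacoustic Index: area under the in-band mean dB spectrum after
    subtracting the band minimum.

    The mean magnitude spectrum is converted to dB, restricted to
    [lo, hi] Hz, shifted so its minimum is 0, and integrated over
    frequency in kHz (trapezoid); units are dB*kHz. Adding a constant
    gain leaves the value unchanged.
    """
    if hi > sig.rate / 2:
        raise ParameterError("band extends beyond Nyquist")
    spec = stft_spectrogram(sig, win_len=win_len, hop=hop, window_fn=window)
    prof = mean_spectrum(spec)
    return _bi_from_profile(prof, lo, hi)


def _bi_from_profile(prof: SpectrumProfile, lo: float, hi: float) -> float:
    mask = (prof.freqs >= lo) & (prof.freqs <= hi)
    power = prof.power[mask]
    if power.size < 2 or power.sum() <= 0:
        raise UndefinedInputError("Bioacoustic Index undefined: silent band")
    db = 20.0 * np.log10(np.maximum(power, 1e-300))
    db -= db.min()
    return float(np.trapezoid(db, prof.freqs[mask] / 1000.0))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def compute_index_report(sig: AudioSignal,
                         config: IndexConfig | None = None) -> IndexReport:
    """Compute all six indices (plus sh, th) with one shared
    preprocessing chain.

    A per-index degenerate input (e.g. silence) does not abort the run:
    the affected values are NaN and the reason is stored in
    ``report.errors``.
    """
    cfg = config or IndexConfig()
    if cfg.highpass_hz is not None:
        sig = highpass_filter(sig, cfg.highpass_hz, cfg.highpass_slope)
    spec = stft_spectrogram(sig, win_len=cfg.win_len, hop=cfg.hop,
                            window_fn=cfg.window)
    prof = mean_spectrum(spec)
    power = (spec.values ** 2).mean(axis=1)

    values: dict[str, float] = {}
    errors: dict[str, str] = {}

    def attempt(name, fn):
        try:
            values[name] = fn()
        except UndefinedInputError as exc:
            values[name] = float("nan")
            errors[name] = str(exc)

    attempt("ndsi", lambda: _ndsi_from_power(power, spec.freqs, cfg.bands))
    attempt("adi", lambda: adi(spec, cfg.adi_bands, cfg.adi_threshold_db))
    attempt("aei", lambda: aei(spec, cfg.adi_bands, cfg.adi_threshold_db))
    attempt("sh", lambda: spectral_entropy(prof))
    attempt("th", lambda: temporal_entropy(amplitude_envelope(sig)))
    values["h"] = values["sh"] * values["th"]
    if "sh" in errors or "th" in errors:
        errors["h"] = "undefined because sh or th is undefined"
    attempt("aci", lambda: aci(spec, cfg.aci_clump_seconds))
    attempt("bi", lambda: _bi_from_profile(prof, cfg.bi_lo, cfg.bi_hi))

    return IndexReport(parameters=cfg.as_dict(), errors=errors, **values)
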