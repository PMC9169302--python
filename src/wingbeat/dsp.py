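"""Spectral feature extraction for wingbeat recordings.

Implements the five-feature chain used for optical wingbeat classification:

1. Welch power spectral density (PSD), 257 values from 512-sample windows.
2. Wingbeat fundamental frequency ``f1`` (Hz), by peak search on the PSD
   within the plausible mosquito range of 300-900 Hz.
3. Fundamental peak power density (dB/Hz re 1.0 unit^2/Hz) at the f1 bin.
4. Short-time spectrogram: nine 512-sample segments of the 1024-sample
   recording (hop 64), amplitude spectra of 257 bins each.
5. MFCCs: 16 triangular Mel filter banks per spectrogram segment,
   log-compressed, decorrelated with a DCT-II, 9 x 16 = 144 values.

All dB values are referenced to a power density of 1.0 unit^2/Hz, so a
full-band white-noise signal of unit density sits at 0 dB/Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy import signal as sps
from scipy.fft import dct, rfft

if TYPE_CHECKING:  # pragma: no cover
    from wingbeat.sensor_sim import WingbeatRecording

RECORD_LENGTH = 1024
WINDOW_LENGTH = 512
SPECTROGRAM_HOP = 64
N_SEGMENTS = (RECORD_LENGTH - WINDOW_LENGTH) // SPECTROGRAM_HOP + 1  # = 9
N_PSD_BINS = WINDOW_LENGTH // 2 + 1  # = 257
N_MEL_BANDS = 16
F1_SEARCH_RANGE = (300.0, 900.0)
LOG_FLOOR = 1e-12
_DB_FLOOR = 1e-30

#: Flat dimension of each feature vector produced by :func:`extract_features`.
FEATURE_DIMS: Mapping[str, int] = {
    "fundamental_frequency": 1,
    "fundamental_peak_power": 1,
    "frequency_and_power": 2,
    "psd": N_PSD_BINS,
    "spectrogram": N_SEGMENTS * N_PSD_BINS,
    "mfcc": N_SEGMENTS * N_MEL_BANDS,
}

FEATURE_NAMES = tuple(FEATURE_DIMS)


@dataclass(frozen=True)
class PSDResult:
    """One-sided Welch power spectral density of a recording."""

    frequencies: np.ndarray  # Hz, 0 .. Nyquist, 257 values
    power_linear: np.ndarray  # unit^2/Hz
    power_db: np.ndarray  # dB/Hz re 1.0 unit^2/Hz

    def __post_init__(self) -> None:
        if not (len(self.frequencies) == len(self.power_linear) == len(self.power_db)):
            raise ValueError("PSD arrays must have equal length")

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class FundamentalPeak:
    """Wingbeat fundamental frequency and its peak power density."""

    f1: float  # Hz
    peak_power_db: float  # dB/Hz


@dataclass(frozen=True)
class SpectrogramResult:
    """Short-time amplitude spectra: ``n_segments x n_bins`` matrix."""

    matrix: np.ndarray  # amplitude spectra, 9 x 257
    segment_offsets: np.ndarray  # start time of each segment, seconds
    sampling_rate: float


@dataclass(frozen=True)
class MelCepstrumResult:
    """Mel-frequency cepstral coefficients: ``n_segments x n_coeffs``."""

    matrix: np.ndarray  # 9 x 16

    @property
    def flat(self) -> np.ndarray:
        """Row-major 144-value feature vector (segment-major order)."""
        return self.matrix.reshape(-1)


@dataclass(frozen=True)
class FeatureVector:
    feature_name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = FEATURE_DIMS.get(self.feature_name)
        if expected is None:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if len(self.values) != expected:
            raise ValueError(
                f"{self.feature_name} expects {expected} values, got {len(self.values)}"
            )


def _as_samples(recording, fs: float | None = None) -> tuple[np.ndarray, float]:
    """Accept a WingbeatRecording or a bare array (with default sensor rate)."""
    if hasattr(recording, "samples"):
        return np.asarray(recording.samples, dtype=float), float(recording.sampling_rate)
    return np.asarray(recording, dtype=float), 9603.0 if fs is None else float(fs)


def baseline_correct(samples: np.ndarray) -> np.ndarray:
    """Remove the DC offset by subtracting the mean of the recording.

    Mirrors the baseline correction applied to raw sensor records before
    display and analysis; the output has zero mean.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot baseline-correct an empty waveform")
    return x - x.mean()


def welch_psd(
    recording, window_length: int = WINDOW_LENGTH, fs: float | None = None
) -> PSDResult:
    """Welch PSD: Hann-windowed overlapping segments, periodograms averaged.

    Uses ``window_length``-sample Hann windows with 50% overlap (three
    segments for a 1024-sample record), density scaling, so white noise of
    variance sigma^2 has mean density ~ sigma^2 / (fs/2) and unit-density
    white noise sits at 0 dB/Hz.
    """
    x, fs = _as_samples(recording, fs)
    if len(x) < window_length:
        raise ValueError(
            f"recording of {len(x)} samples is shorter than the {window_length}-sample window"
        )
    freqs, pxx = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=window_length,
        noverlap=window_length // 2,
        detrend=False,
        scaling="density",
    )
    power_db = 10.0 * np.log10(np.maximum(pxx, _DB_FLOOR))
    return PSDResult(frequencies=freqs, power_linear=pxx, power_db=power_db)


def find_fundamental(
    psd: PSDResult, search_range: tuple[float, float] = F1_SEARCH_RANGE
) -> FundamentalPeak:
    """Locate the wingbeat fundamental as the strongest PSD bin in range.

    The search is a plain global maximum within ``search_range`` (inclusive);
    ties break toward the lower frequency and no sub-bin interpolation is
    applied. ``peak_power_db`` is the dB/Hz value at the winning bin.
    """
    lo, hi = search_range
    mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"no PSD bin inside the search range [{lo}, {hi}] Hz")
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(psd.power_db[idx]))]  # argmax takes first -> lower f
    return FundamentalPeak(
        f1=float(psd.frequencies[best]), peak_power_db=float(psd.power_db[best])
    )


def _segments(x: np.ndarray) -> np.ndarray:
    if len(x) != RECORD_LENGTH:
        raise ValueError(f"expected a {RECORD_LENGTH}-sample recording, got {len(x)}")
    starts = np.arange(N_SEGMENTS) * SPECTROGRAM_HOP
    return np.stack([x[s : s + WINDOW_LENGTH] for s in starts])


def compute_spectrogram(recording, fs: float | None = None) -> SpectrogramResult:
    """Nine overlapping 512-sample amplitude spectra of a 1024-sample record.

    Segment ``k`` covers samples ``[64k, 64k + 512)``; each segment is Hann
    windowed and Fourier transformed, and the one-sided amplitude spectrum
    (257 bins) is kept.
    """
    x, fs = _as_samples(recording, fs)
    segs = _segments(x)
    win = sps.get_window("hann", WINDOW_LENGTH)
    spectra = np.abs(rfft(segs * win, axis=1))
    offsets = np.arange(N_SEGMENTS) * SPECTROGRAM_HOP / fs
    return SpectrogramResult(matrix=spectra, segment_offsets=offsets, sampling_rate=fs)


def mel_scale(f: np.ndarray) -> np.ndarray:
    """Hz -> Mel, conventional formula ``2595 log10(1 + f/700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filter_bank(
    n_bands: int = N_MEL_BANDS,
    n_bins: int = N_PSD_BINS,
    fs: float = 9603.0,
) -> np.ndarray:
    """Triangular Mel filter bank, ``n_bands x n_bins``, spanning 0..Nyquist.

    Band centres are equally spaced on the Mel scale; each triangle rises
    from the previous centre to its own and falls to the next, with unit
    peak amplitude, so adjacent filters overlap.
    """
    nyquist = fs / 2.0
    mel_pts = np.linspace(mel_scale(0.0), mel_scale(nyquist), n_bands + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.linspace(0.0, nyquist, n_bins)
    bank = np.zeros((n_bands, n_bins))
    for b in range(n_bands):
        left, centre, right = hz_pts[b], hz_pts[b + 1], hz_pts[b + 2]
        rise = (freqs - left) / (centre - left)
        fall = (right - freqs) / (right - centre)
        bank[b] = np.clip(np.minimum(rise, fall), 0.0, None)
    return bank


def compute_mfcc(
    recording, n_mels: int = N_MEL_BANDS, fs: float | None = None
) -> MelCepstrumResult:
    """MFCCs from the nine-segment spectrogram: 9 x ``n_mels`` coefficients.

    Per segment: power spectrum -> triangular Mel filter bank energies ->
    log with an additive floor (so silent segments are well defined) ->
    DCT-II (orthonormal) as the cepstral transform. The standard DCT
    realizes the inverse transform of a real, even log-spectrum.
    """
    x, fs = _as_samples(recording, fs)
    spec = compute_spectrogram(x, fs=fs)
    power = spec.matrix**2
    bank = mel_filter_bank(n_bands=n_mels, fs=fs)
    energies = power @ bank.T  # 9 x n_mels
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    return MelCepstrumResult(matrix=ceps)


def extract_features(
    recording, spectrogram_scale: str = "log-power"
) -> dict[str, FeatureVector]:
    """Compute all six model-input feature vectors for one recording.

    Returns a dict keyed by feature name with dimensions 1 / 1 / 2 / 257 /
    2313 / 144. The recording is baseline corrected first. The combined
    feature is ``(f1, peak_power_db)``. The spectrogram is flattened
    segment-major, by default in log-power (dB) scale; ``"amplitude"`` and
    ``"power"`` are also accepted.
    """
    x, fs = _as_samples(recording)
    x = baseline_correct(x)
    psd = welch_psd(x, fs=fs)
    peak = find_fundamental(psd)
    spec = compute_spectrogram(x, fs=fs)
    if spectrogram_scale == "log-power":
        spec_values = 10.0 * np.log10(np.maximum(spec.matrix**2, _DB_FLOOR))
    elif spectrogram_scale == "power":
        spec_values = spec.matrix**2
    elif spectrogram_scale == "amplitude":
        spec_values = spec.matrix
    else:
        raise ValueError(f"unknown spectrogram scale {spectrogram_scale!r}")
    mfcc = compute_mfcc(x, fs=fs)
    return {
        "fundamental_frequency": FeatureVector("fundamental_frequency", np.array([peak.f1])),
        "fundamental_peak_power": FeatureVector(
            "fundamental_peak_power", np.array([peak.peak_power_db])
        ),
        "frequency_and_power": FeatureVector(
            "frequency_and_power", np.array([peak.f1, peak.peak_power_db])
        ),
        "psd": FeatureVector("psd", psd.power_db.copy()),
        "spectrogram": FeatureVector("spectrogram", spec_values.reshape(-1)),
        "mfcc": FeatureVector("mfcc", mfcc.flat.copy()),
    }
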