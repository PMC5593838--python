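"""Spectral feature extraction from QRS (and R-centred) segments.

Twelve features per lead are computed from each segment with four
time-frequency views:

* FFT — power summed in three bands classically used for conventional and
  high-frequency QRS analysis: 0-35, 35-90 and 125-250 Hz.
* STFT — mean, median and maximum of the magnitude spectrogram
  (32-sample Hamming window, 75 % overlap, 128-point FFT), DC row
  excluded.
* CWT — symlet-2 wavelet at all integer scales 1-32: mean and maximum of
  the |coefficient| matrix, plus two normalized-correlation features:
  the mean over scales of the best-placement correlation, and the mean
  over placements of the best-scale correlation.
* Wigner-Ville — maximum and mean magnitude of the discrete
  Wigner-Ville distribution of the analytic segment in 0-500 Hz.

``extract_spectrald`` applies the battery to the delineated QRS
([onset, J)) of both leads (24 features); ``extract_spectralr`` applies
it to <R-t, R+t> segments for t = 20, 30, 50 ms (72 features, subgroups
S20/S30/S50).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import correlate, hilbert

from .registry import FeatureVector, registry_names
from .synthetic import Fiducials, SyntheticBeat

__all__ = [
    "DEFAULT_BANDS",
    "fft_band_sums",
    "stft_stats",
    "cwt_features",
    "wvd_features",
    "spectral_battery",
    "extract_spectrald",
    "extract_spectralr",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.0, 35.0), (35.0, 90.0), (125.0, 250.0))
_FFT_NFFT = 4096
_STFT_WINDOW = 32
_STFT_HOP = 8          # 75 % overlap
_STFT_NFFT = 128
_CWT_SCALES = tuple(range(1, 33))
_WVD_FMAX = 500.0


def fft_band_sums(
    segment: np.ndarray,
    fs: float,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    nfft: int = _FFT_NFFT,
) -> np.ndarray:
    """One-sided power summed over each [low, high) band.

    The segment is zero-padded to a fixed ``nfft`` so band resolution does
    not depend on segment duration; interior bins carry the factor 2 of
    the one-sided spectrum.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError("segment too short for a spectrum")
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    weights = np.full(spec.shape, 2.0)
    weights[0] = 1.0
    if nfft % 2 == 0:
        weights[-1] = 1.0
    spec = spec * weights
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    out = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        out[i] = spec[(freqs >= lo) & (freqs < hi)].sum()
    return out


def _frames(x: np.ndarray, width: int, hop: int) -> np.ndarray:
    """Frame a signal; a too-short signal yields one zero-padded frame."""
    if len(x) < width:
        return np.pad(x, (0, width - len(x)))[None, :]
    n = 1 + (len(x) - width) // hop
    idx = hop * np.arange(n)[:, None] + np.arange(width)[None, :]
    return x[idx]


def stft_stats(
    segment: np.ndarray,
    fs: float,
    window: int = _STFT_WINDOW,
    hop: int = _STFT_HOP,
    nfft: int = _STFT_NFFT,
) -> tuple[float, float, float]:
    """(mean, median, max) of the magnitude spectrogram, DC row excluded."""
    x = np.asarray(segment, dtype=float)
    frames = _frames(x, window, hop) * np.hamming(window)
    mag = np.abs(np.fft.rfft(frames, n=nfft, axis=1))[:, 1:]  # drop DC
    return float(mag.mean()), float(np.median(mag)), float(mag.max())


@lru_cache(maxsize=64)
def _sym2_kernel(scale: int) -> np.ndarray:
    """sym2 wavelet sampled at integer points for one scale, L2-normalised
    by 1/sqrt(scale); support truncated below 1e-8 amplitude."""
    wavelet = pywt.Wavelet("sym2")
    _, psi, grid = wavelet.wavefun(level=10)
    support = grid[-1]  # sym2: [0, 3]
    t = np.arange(int(np.ceil(support * scale)) + 1) / scale
    k = np.interp(t, grid, psi) / np.sqrt(scale)
    big = np.flatnonzero(np.abs(k) > 1e-8)
    return k[big[0]:big[-1] + 1] if big.size else k[:1]


def _centered_correlation(seg: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation of ``seg`` with ``kernel`` centred at each segment sample.

    out[p] = sum_m kernel[m] * seg[p - (K-1)//2 + m] with zero padding.
    """
    n, K = len(seg), len(kernel)
    full = correlate(seg, kernel, mode="full", method="direct")
    start = K - 1 - (K - 1) // 2
    return full[start:start + n]


def cwt_features(
    segment: np.ndarray,
    fs: float,
    scales: tuple[int, ...] = _CWT_SCALES,
) -> tuple[float, float, float, float]:
    """(mean |CWT|, max |CWT|, corr_bestpos, corr_bestscale).

    The correlation matrix r[a, p] is the normalized correlation between
    the segment and the scale-a wavelet centred at sample p (Cauchy-
    Schwarz bounds it to [-1, 1]).  ``corr_bestpos`` averages over scales
    the best correlation across placements; ``corr_bestscale`` averages
    over placements the best correlation across scales.  A zero segment
    returns all zeros.
    """
    x = np.asarray(segment, dtype=float)
    norm_x = np.linalg.norm(x)
    coeffs = np.empty((len(scales), len(x)))
    corr = np.zeros((len(scales), len(x)))
    for i, a in enumerate(scales):
        kern = _sym2_kernel(int(a))
        c = _centered_correlation(x, kern)
        coeffs[i] = c
        if norm_x > 0:
            corr[i] = c / (norm_x * np.linalg.norm(kern))
    absc = np.abs(coeffs)
    if norm_x == 0:
        return 0.0, 0.0, 0.0, 0.0
    bestpos = float(corr.max(axis=1).mean())
    bestscale = float(corr.max(axis=0).mean())
    return float(absc.mean()), float(absc.max()), bestpos, bestscale


def wvd_features(
    segment: np.ndarray,
    fs: float,
    fmax: float = _WVD_FMAX,
) -> tuple[float, float]:
    """(max, mean) magnitude of the discrete Wigner-Ville distribution.

    Uses the analytic signal to suppress aliasing and cross-terms between
    positive and negative frequencies.  With the instantaneous
    autocorrelation r_n[m] = z[n+m] z*[n-m], bin k of the M-point DFT over
    the lag m maps to frequency k * fs / (2 M); statistics are taken over
    cells with frequency in [0, fmax].
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 8:
        raise ValueError("segment too short for a Wigner-Ville distribution")
    z = hilbert(x)
    n = len(z)
    M = 2 * n
    lagmat = np.zeros((M, n), dtype=complex)
    for t in range(n):
        h = min(t, n - 1 - t)
        m = np.arange(-h, h + 1)
        lagmat[m % M, t] = z[t + m] * np.conj(z[t - m])
    W = np.fft.fft(lagmat, axis=0)
    freqs = np.arange(M) * fs / (2.0 * M)
    mag = np.abs(W[freqs <= fmax, :])
    return float(mag.max()), float(mag.mean())


def spectral_battery(segment: np.ndarray, fs: float) -> dict[str, float]:
    """The 12-feature battery for a single-lead segment."""
    f = fft_band_sums(segment, fs)
    s_mean, s_med, s_max = stft_stats(segment, fs)
    c_mean, c_max, c_bp, c_bs = cwt_features(segment, fs)
    w_max, w_mean = wvd_features(segment, fs)
    return {
        "fft_0_35": float(f[0]), "fft_35_90": float(f[1]), "fft_125_250": float(f[2]),
        "stft_mean": s_mean, "stft_median": s_med, "stft_max": s_max,
        "cwt_mean": c_mean, "cwt_max": c_max,
        "cwt_corr_bestpos": c_bp, "cwt_corr_bestscale": c_bs,
        "wvd_max": w_max, "wvd_mean": w_mean,
    }


def extract_spectrald(
    beat: SyntheticBeat | np.ndarray,
    fiducials: Fiducials | None = None,
    fs: float | None = None,
    beat_id: int | None = None,
) -> FeatureVector:
    """24 spectral features from the delineated QRS ([onset, J)) of both leads."""
    if isinstance(beat, SyntheticBeat):
        window, fiducials, fs, label = beat.waveform, beat.fiducials, beat.fs, beat.label
    else:
        window, label = np.atleast_2d(np.asarray(beat, dtype=float)), None
    if fiducials is None or fs is None:
        raise ValueError("fiducials and fs are required for raw windows")
    if fiducials.j_point - fiducials.qrs_onset < 4:
        raise ValueError("QRS interval is empty or too short")
    vals: dict[str, float] = {}
    for li, lead in enumerate(("i", "ii")):
        seg = window[li, fiducials.qrs_onset:fiducials.j_point]
        for stem, v in spectral_battery(seg, fs).items():
            vals[f"d_{stem}_{lead}"] = v
    vals = {k: vals[k] for k in registry_names("SpectralD")}
    return FeatureVector(values=vals, beat_id=beat_id, label=label)


def extract_spectralr(
    beat: SyntheticBeat | np.ndarray,
    r_index: int | None = None,
    fs: float | None = None,
    t_values_ms: tuple[int, ...] = (20, 30, 50),
    beat_id: int | None = None,
) -> FeatureVector:
    """Spectral battery on <R-t, R+t> segments, 24 features per t value."""
    if isinstance(beat, SyntheticBeat):
        window, fs, label = beat.waveform, beat.fs, beat.label
        r_index = beat.fiducials.r_peak
    else:
        window, label = np.atleast_2d(np.asarray(beat, dtype=float)), None
    if r_index is None or fs is None:
        raise ValueError("r_index and fs are required for raw windows")
    L = window.shape[-1]
    vals: dict[str, float] = {}
    for t in t_values_ms:
        h = int(round(t / 1000.0 * fs))
        lo, hi = max(0, r_index - h), min(L, r_index + h + 1)
        for li, lead in enumerate(("i", "ii")):
            for stem, v in spectral_battery(window[li, lo:hi], fs).items():
                vals[f"s{t}_{stem}_{lead}"] = v
    expected = [n for n in registry_names("SpectralR")
                if any(n.startswith(f"s{t}_") for t in t_values_ms)]
    vals = {k: vals[k] for k in expected}
    return FeatureVector(values=vals, beat_id=beat_id, label=label)
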