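"""Morphological feature extraction.

Two families are computed from a 280 ms two-lead beat window:

* ``extract_morphd`` needs the delineated landmarks (QRS onset, R peak,
  J point, T end) and emits 71 features: interval durations, two-lead
  QRS/ST-T loop geometry, per-lead voltage deviations (amplitudes
  referenced to the pre-QRS isoline) and a family of trapezoidal areas
  under signed, rectified and absolute parts of the QRS, ST-T and whole
  QRS-T intervals, with relative values and positive-to-negative ratios.

* ``extract_morphr`` needs only the R position and emits 44 features:
  extremum values/positions over the whole window and areas over
  <R-t, R+t> windows (t = 40, 60, 100 ms) chosen to capture the QRS, the
  QRS with adjacent ST, and almost the whole QRS-T respectively.

Areas are computed exactly on the piecewise-linear interpolant of the
sampled waveform (zero crossings split analytically), so the identities
signed = positive + negative and absolute = positive - negative hold to
machine precision.
"""

from __future__ import annotations

import numpy as np

from .registry import FeatureVector, RATIO_SENTINEL, registry_names
from .synthetic import Fiducials, SyntheticBeat

__all__ = [
    "area_under",
    "loop_features",
    "extract_morphd",
    "extract_morphr",
    "isoline",
]

_ISOLINE_MS = 10.0


def isoline(window: np.ndarray, fs: float) -> np.ndarray:
    """Per-lead isoelectric reference: median of the first 10 ms."""
    n = max(1, int(round(_ISOLINE_MS / 1000.0 * fs)))
    return np.median(np.atleast_2d(window)[:, :n], axis=1)


def area_under(samples: np.ndarray, fs: float, part: str = "signed") -> float:
    """Area (mV.s) under the piecewise-linear interpolant of ``samples``.

    ``part`` selects the signed area, its positive or negative component
    (crossing segments split at the analytic zero crossing), or the
    absolute area (= positive - negative).
    """
    v = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("samples must be finite")
    if v.size < 2:
        return 0.0
    dt = 1.0 / fs
    v0, v1 = v[:-1], v[1:]
    signed_seg = 0.5 * (v0 + v1) * dt
    if part == "signed":
        return float(signed_seg.sum())
    # positive part of each linear segment
    both_pos = (v0 >= 0) & (v1 >= 0)
    both_neg = (v0 <= 0) & (v1 <= 0)
    cross = ~(both_pos | both_neg)
    pos_seg = np.where(both_pos, signed_seg, 0.0)
    if np.any(cross):
        a, b = v0[cross], v1[cross]
        frac = a / (a - b)  # crossing position within the segment
        pos_tri = np.where(a > 0, 0.5 * a * frac * dt, 0.5 * b * (1.0 - frac) * dt)
        tmp = np.zeros_like(pos_seg)
        tmp[cross] = pos_tri
        pos_seg = pos_seg + tmp
    pos = float(pos_seg.sum())
    if part == "positive":
        return pos
    neg = float(signed_seg.sum()) - pos
    if part == "negative":
        return neg
    if part == "absolute":
        return pos - neg
    raise ValueError(f"unknown part {part!r}")


def loop_features(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Length and angle (deg) of the maximal two-lead voltage vector.

    Treats (lead I, lead II) as orthogonal horizontal-plane coordinates.
    The all-zero loop returns (0, 0) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("leads must cover the same interval")
    r = np.hypot(x, y)
    k = int(np.argmax(r))
    if r[k] == 0.0:
        return 0.0, 0.0
    return float(r[k]), float(np.degrees(np.arctan2(y[k], x[k])))


def _ratio(pos: float, neg: float) -> float:
    """Positive-to-negative area ratio with a capped sentinel at 0 denominator."""
    denom = -neg
    if denom < 1e-12:
        return RATIO_SENTINEL
    return min(pos / denom, RATIO_SENTINEL)


def _rel(value: float, denom: float) -> float:
    if abs(denom) < 1e-12:
        if value == 0.0:
            return 0.0
        return float(np.sign(value)) * RATIO_SENTINEL
    return float(np.clip(value / denom, -RATIO_SENTINEL, RATIO_SENTINEL))


def _coerce(beat, fiducials=None, fs=None):
    if isinstance(beat, SyntheticBeat):
        return beat.waveform, beat.fiducials, beat.fs, beat.label
    return np.atleast_2d(np.asarray(beat, dtype=float)), fiducials, fs, None


def extract_morphd(
    beat: SyntheticBeat | np.ndarray,
    fiducials: Fiducials | None = None,
    fs: float | None = None,
    beat_id: int | None = None,
) -> FeatureVector:
    """71 delineation-based morphological features for one beat."""
    window, fid, fs, label = _coerce(beat, fiducials, fs)
    if fid is None or fs is None:
        raise ValueError("fiducials and fs are required for raw windows")
    L = window.shape[-1]
    if not (0 <= fid.qrs_onset and fid.t_end < L):
        raise ValueError("fiducials outside the beat window")
    iso = isoline(window, fs)
    dev = window - iso[:, None]

    on, j, te = fid.qrs_onset, fid.j_point, fid.t_end
    qrs = dev[:, on:j + 1]
    stt = dev[:, j:te + 1]
    qrst = dev[:, on:te + 1]

    vals: dict[str, float] = {}
    vals["qrs_d_ms"] = (j - on) / fs * 1000.0
    vals["qt_ms"] = (te - on) / fs * 1000.0
    # J point to the maximal absolute ST-T deviation (lead-summed magnitude)
    stt_mag = np.abs(stt).sum(axis=0)
    vals["jtmax_ms"] = int(np.argmax(stt_mag)) / fs * 1000.0
    qlen, qang = loop_features(qrs[0], qrs[1])
    slen, sang = loop_features(stt[0], stt[1])
    vals["qrsloop_len_mv"], vals["qrsloop_angle_deg"] = qlen, qang
    vals["sttloop_len_mv"], vals["sttloop_angle_deg"] = slen, sang

    for li, lead in enumerate(("i", "ii")):
        q, s, w = qrs[li], stt[li], qrst[li]
        vals[f"qrs_pos_amp_{lead}"] = float(max(q.max(), 0.0))
        vals[f"qrs_neg_amp_{lead}"] = float(min(q.min(), 0.0))
        vals[f"qrs_max_abs_{lead}"] = float(np.abs(q).max())
        # T amplitude: signed extremum over the T-wave region (skipping the
        # early ST plateau); ST-T maximal deviation over the whole J..Tend
        t_reg = s[len(s) // 3:]
        vals[f"t_amp_{lead}"] = float(t_reg[np.argmax(np.abs(t_reg))]) if t_reg.size else 0.0
        vals[f"stt_maxdev_{lead}"] = float(s[np.argmax(np.abs(s))])
        vals[f"stt_maxdev_abs_{lead}"] = float(np.abs(s).max())
        k20 = j + int(round(0.020 * fs))
        vals[f"st20_{lead}"] = float(dev[li, min(k20, L - 1)])

        areas: dict[str, dict[str, float]] = {}
        for name, seg in (("qrs", q), ("stt", s), ("qrst", w)):
            areas[name] = {p: area_under(seg, fs, p) for p in ("signed", "positive", "negative", "absolute")}
            vals[f"auc_{name}_{lead}"] = areas[name]["signed"]
            vals[f"auc_{name}_pos_{lead}"] = areas[name]["positive"]
            vals[f"auc_{name}_neg_{lead}"] = areas[name]["negative"]
            vals[f"auc_{name}_abs_{lead}"] = areas[name]["absolute"]
        total = areas["qrst"]["signed"]
        for rel, (name, p) in {
            "qrs": ("qrs", "signed"), "qrs_pos": ("qrs", "positive"),
            "qrs_neg": ("qrs", "negative"), "qrs_abs": ("qrs", "absolute"),
            "stt": ("stt", "signed"), "stt_pos": ("stt", "positive"),
            "stt_neg": ("stt", "negative"), "stt_abs": ("stt", "absolute"),
            "qrst_pos": ("qrst", "positive"), "qrst_neg": ("qrst", "negative"),
        }.items():
            vals[f"auc_{rel}_rel_{lead}"] = _rel(areas[name][p], total)
        for name in ("qrs", "stt", "qrst"):
            vals[f"auc_{name}_ratio_{lead}"] = _ratio(areas[name]["positive"], areas[name]["negative"])

    expected = registry_names("MorphD")
    vals = {k: vals[k] for k in expected}
    return FeatureVector(values=vals, beat_id=beat_id, label=label)


def extract_morphr(
    beat: SyntheticBeat | np.ndarray,
    r_index: int | None = None,
    fs: float | None = None,
    beat_id: int | None = None,
) -> FeatureVector:
    """44 R-peak-based morphological features for one beat.

    All positions are expressed in ms relative to the R peak, and all
    windows are taken relative to the R index, so translating the window
    together with ``r_index`` leaves every feature unchanged.
    """
    if isinstance(beat, SyntheticBeat):
        window, fs = beat.waveform, beat.fs
        r_index = beat.fiducials.r_peak
        label = beat.label
    else:
        window = np.atleast_2d(np.asarray(beat, dtype=float))
        label = None
    if r_index is None or fs is None:
        raise ValueError("r_index and fs are required for raw windows")
    L = window.shape[-1]
    if not 0 <= r_index < L:
        raise ValueError("r_index outside the window")

    vals: dict[str, float] = {}
    for li, lead in enumerate(("i", "ii")):
        v = window[li]
        kmax = int(np.argmax(v))
        kmin = int(np.argmin(v))
        vals[f"r_max_{lead}"] = float(v[kmax])
        vals[f"r_max_pos_{lead}"] = (kmax - r_index) / fs * 1000.0
        vals[f"r_min_{lead}"] = float(v[kmin])
        vals[f"r_min_pos_{lead}"] = (kmin - r_index) / fs * 1000.0
        vals[f"r_range_{lead}"] = float(v[kmax] - v[kmin])
        vals[f"r_minmax_dt_{lead}"] = abs(kmax - kmin) / fs * 1000.0

        def t_window(t_ms: float) -> np.ndarray:
            h = int(round(t_ms / 1000.0 * fs))
            return v[max(0, r_index - h):min(L, r_index + h + 1)]

        for t in (40, 60, 100):
            vals[f"auc_r{t}_{lead}"] = area_under(t_window(t), fs, "signed")
        full_signed = area_under(v, fs, "signed")
        full_pos = area_under(v, fs, "positive")
        full_abs = area_under(v, fs, "absolute")
        vals[f"auc_rfull_{lead}"] = full_signed
        vals[f"auc_rfull_pos_{lead}"] = full_pos
        vals[f"auc_rfull_neg_{lead}"] = full_signed - full_pos
        for t in (40, 60, 100):
            vals[f"auc_r{t}_rel_{lead}"] = _rel(vals[f"auc_r{t}_{lead}"], full_signed)
        for t in (40, 60, 100):
            vals[f"absauc_r{t}_{lead}"] = area_under(t_window(t), fs, "absolute")
        vals[f"absauc_rfull_{lead}"] = full_abs
        for t in (40, 60, 100):
            vals[f"absauc_r{t}_rel_{lead}"] = _rel(vals[f"absauc_r{t}_{lead}"], full_abs)

    expected = registry_names("MorphR")
    vals = {k: vals[k] for k in expected}
    return FeatureVector(values=vals, beat_id=beat_id, label=label)
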