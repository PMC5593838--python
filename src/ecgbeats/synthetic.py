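"""Synthetic two-lead ECG beat and record generation.

Emulates four heartbeat morphologies observed in isolated-heart recordings
under global ischemia: non-ischemic sinus beats (NOR), moderate ischemic
beats (ISM, slight ST deviation and mild QRS prolongation), severe ischemic
beats (ISE, prominent ST deviation, QRS widening, inverted T) and
ventricular premature beats (VPB, wide bizarre biphasic complexes with
discordant T, premature timing).

Each beat is a 280 ms two-lead window (30 ms before to 250 ms after the
R peak) built as a sum of compactly-supported Gaussian-shaped bumps for the
Q, R, S and T deflections plus a smooth ST-plateau offset between the
J point and the T-wave onset.  Because every bump has strictly finite
support, the ground-truth fiducials (QRS onset, R peak, J point, T end) are
exact analytic landmarks of the construction, and the ST-segment offset
20 ms after the J point equals the drawn ST level exactly in the noiseless
case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "BeatClass",
    "ClassMorphology",
    "GeneratorConfig",
    "Fiducials",
    "SyntheticBeat",
    "SyntheticRecord",
    "default_config",
    "generate_beat",
    "generate_dataset",
    "generate_record",
]

#: minimum physiologically plausible R-R interval (ms) for rabbit hearts
MIN_RR_MS = 150.0

#: truncation of per-beat parameter draws, in standard deviations
_TRUNC_SD = 3.0


class BeatClass(IntEnum):
    """The four beat classes; integer codes index confusion matrices."""

    NOR = 0
    ISM = 1
    ISE = 2
    VPB = 3


@dataclass(frozen=True)
class ClassMorphology:
    """Per-class waveform parameters.

    Durations are in ms, voltages in mV.  Per-lead quantities are
    ``(lead I, lead II)`` pairs.  ``r_frac`` is the fraction of the QRS
    duration preceding the R peak.  ``trunc_sd`` bounds per-beat draws to
    ``mean +/- trunc_sd * sd`` (symmetric, so class means are unbiased).
    """

    rr_mean_ms: float
    rr_sd_ms: float
    qrs_dur_mean_ms: float
    qrs_dur_sd_ms: float
    qt_mean_ms: float
    qt_sd_ms: float
    r_amp: tuple[float, float]
    q_amp: tuple[float, float]
    s_amp: tuple[float, float]
    t_amp: tuple[float, float]
    st_level: tuple[float, float] = (0.0, 0.0)
    st_sd: float = 0.0
    r_frac: float = 0.5
    amp_jitter_frac: float = 0.0
    prematurity_frac: float | None = None
    trunc_sd: float = _TRUNC_SD
    #: per-heart morphology modes, drawn uniformly per beat; each mode may
    #: scale amplitudes (amp), the ST level (st, sign included), the T wave
    #: (t) and flip QRS polarity (pol = -1).  Emulates the strong
    #: inter-experiment variability of multi-heart recordings.
    modes: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.qrs_dur_mean_ms <= 0 or self.qt_mean_ms <= 0 or self.rr_mean_ms <= 0:
            raise ValueError("durations must be positive")
        if self.qrs_dur_mean_ms >= self.qt_mean_ms:
            raise ValueError("QRS duration must be shorter than QT")
        if self.rr_mean_ms <= self.qt_mean_ms:
            raise ValueError("RR must exceed QT")
        if not 0.0 < self.r_frac < 1.0:
            raise ValueError("r_frac must lie in (0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration: sampling, per-class morphology, noise."""

    fs: float = 2000.0
    classes: dict[BeatClass, ClassMorphology] = field(default_factory=dict)
    noise_sd: float = 0.02
    baseline_amp: float = 0.0
    baseline_freq: float = 0.3
    quantize_bits: int | None = None
    quantize_step_mv: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValueError("sampling rate must be >= 1000 Hz")
        if not 0 <= self.baseline_freq < 0.5:
            raise ValueError("baseline wander frequency must be < 0.5 Hz")

    @property
    def window_samples(self) -> int:
        return int(round(0.280 * self.fs))

    @property
    def r_index(self) -> int:
        return int(round(0.030 * self.fs))


@dataclass(frozen=True)
class Fiducials:
    """Ground-truth landmarks as 0-based sample indices in a beat window."""

    qrs_onset: int
    r_peak: int
    j_point: int
    t_end: int

    def __post_init__(self) -> None:
        if not self.qrs_onset < self.r_peak < self.j_point < self.t_end:
            raise ValueError("fiducials must satisfy onset < R < J < Tend")

    def shifted(self, offset: int) -> "Fiducials":
        return Fiducials(
            self.qrs_onset + offset,
            self.r_peak + offset,
            self.j_point + offset,
            self.t_end + offset,
        )


@dataclass(frozen=True)
class SyntheticBeat:
    """A two-lead 280 ms beat window with ground truth."""

    waveform: np.ndarray  # shape (2, L), mV
    fiducials: Fiducials
    label: BeatClass
    rr_prev_ms: float
    fs: float
    params: dict = field(default_factory=dict)  # the drawn per-beat values


@dataclass(frozen=True)
class SyntheticRecord:
    """A continuous two-lead record with per-beat annotations."""

    signal: np.ndarray  # shape (2, N), mV
    fs: float
    annotations: list[tuple[int, BeatClass, Fiducials]]


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default study conditions.

    NOR intervals reproduce the stabilization-period statistics of rabbit
    isolated hearts (RR 344 +/- 46 ms, QRS 24 +/- 4 ms, QT 175 +/- 22 ms).
    Ischemic classes shift ST level, widen the QRS and (severe grade)
    invert the T wave; VPBs are wide biphasic complexes arriving early.
    Lead II amplitudes are 1.2x lead I so two-lead loop features are
    non-degenerate.
    """
    lead2 = 1.2
    classes = {
        BeatClass.NOR: ClassMorphology(
            rr_mean_ms=344.0, rr_sd_ms=46.0,
            qrs_dur_mean_ms=24.0, qrs_dur_sd_ms=4.0,
            qt_mean_ms=175.0, qt_sd_ms=22.0,
            r_amp=(1.0, 1.0 * lead2), q_amp=(-0.06, -0.07),
            s_amp=(-0.18, -0.22), t_amp=(0.28, 0.33),
            st_level=(0.0, 0.0), st_sd=0.02,
            r_frac=0.5, amp_jitter_frac=0.12,
            modes=(
                {"amp": 0.75, "t": 0.8}, {"amp": 0.95, "t": 1.0},
                {"amp": 1.10, "t": 1.2}, {"amp": 1.30, "t": 1.0},
            ),
        ),
        BeatClass.ISM: ClassMorphology(
            rr_mean_ms=360.0, rr_sd_ms=50.0,
            qrs_dur_mean_ms=28.0, qrs_dur_sd_ms=5.0,
            qt_mean_ms=170.0, qt_sd_ms=22.0,
            r_amp=(0.95, 0.95 * lead2), q_amp=(-0.06, -0.07),
            s_amp=(-0.22, -0.26), t_amp=(0.25, 0.30),
            st_level=(-0.08, 0.10), st_sd=0.035,
            r_frac=0.5, amp_jitter_frac=0.14,
            modes=(
                {"amp": 1.00, "st": 1.0, "t": 1.0},
                {"amp": 0.85, "st": -1.0, "t": 0.9},
                {"amp": 1.15, "st": 1.3, "t": 0.7},
                {"amp": 0.75, "st": -0.7, "t": 1.1},
            ),
        ),
        BeatClass.ISE: ClassMorphology(
            rr_mean_ms=400.0, rr_sd_ms=60.0,
            qrs_dur_mean_ms=40.0, qrs_dur_sd_ms=6.0,
            qt_mean_ms=155.0, qt_sd_ms=20.0,
            r_amp=(0.80, 0.80 * lead2), q_amp=(-0.05, -0.06),
            s_amp=(-0.35, -0.42), t_amp=(-0.30, -0.36),
            st_level=(-0.25, 0.30), st_sd=0.06,
            r_frac=0.45, amp_jitter_frac=0.16,
            modes=(
                {"amp": 0.90, "st": 1.0, "t": 1.0},
                {"amp": 1.10, "st": -1.0, "t": 0.8},
                {"amp": 0.75, "st": 1.4, "t": 1.2},
                {"amp": 1.25, "st": -0.8, "t": 0.6},
            ),
        ),
        BeatClass.VPB: ClassMorphology(
            rr_mean_ms=241.0, rr_sd_ms=25.0,
            qrs_dur_mean_ms=70.0, qrs_dur_sd_ms=4.0,
            qt_mean_ms=200.0, qt_sd_ms=15.0,
            r_amp=(0.90, 0.90 * lead2), q_amp=(-0.04, -0.05),
            s_amp=(-1.40, -1.65), t_amp=(0.45, 0.52),
            st_level=(0.05, 0.06), st_sd=0.04,
            r_frac=0.30, amp_jitter_frac=0.18,
            prematurity_frac=0.7, trunc_sd=2.5,
            modes=(
                {"amp": 1.00, "pol": 1}, {"amp": 1.20, "pol": -1},
                {"amp": 0.80, "pol": 1}, {"amp": 1.10, "pol": -1},
            ),
        ),
    }
    return GeneratorConfig(fs=2000.0, classes=classes, seed=seed)


def _as_rng(rng: np.random.Generator | int | None, seed: int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        return np.random.default_rng(seed)
    return np.random.default_rng(rng)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, k: float) -> float:
    """Draw from N(mean, sd) clipped symmetrically at mean +/- k*sd."""
    if sd <= 0:
        return mean
    return float(np.clip(rng.normal(mean, sd), mean - k * sd, mean + k * sd))


def _bump(n: np.ndarray, center: float, half_width: float, amp: float) -> np.ndarray:
    """Gaussian-shaped bump with compact support |n - center| < half_width.

    The Gaussian is truncated at 3 sigma and shifted so it reaches zero
    continuously at the support boundary; outside the support it is
    exactly zero, which keeps the analytic fiducials exact.
    """
    if half_width <= 0:
        return np.zeros_like(n, dtype=float)
    z = (n - center) / half_width  # in [-1, 1] within support
    k = 3.0
    base = np.exp(-0.5 * (k * z) ** 2)
    edge = np.exp(-0.5 * k * k)
    out = amp * (base - edge) / (1.0 - edge)
    out[np.abs(z) >= 1.0] = 0.0
    return out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _st_plateau(n: np.ndarray, j: float, t_end: float, level: float, fs: float) -> np.ndarray:
    """ST offset: 0 at J, full level by J+10 ms, back to 0 at T end."""
    ramp = min(10e-3 * fs, 0.25 * (t_end - j))
    up = _smoothstep((n - j) / ramp)
    down = _smoothstep((t_end - n) / ramp)
    out = level * np.minimum(up, down)
    out[(n <= j) | (n >= t_end)] = 0.0
    return out


def generate_beat(
    label: BeatClass,
    config: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
) -> SyntheticBeat:
    """Generate one beat window of class ``label``.

    Per-beat interval and amplitude parameters are drawn from the class
    distributions (truncated at ``trunc_sd`` standard deviations); the
    fiducials returned are the exact landmarks of the constructed bumps.
    Measurement noise is added after the fiducials are fixed.
    """
    morph = config.classes[label]
    rng = _as_rng(rng, config.seed)
    fs = config.fs
    L = config.window_samples
    r_idx = config.r_index

    qrs_ms = _trunc_normal(rng, morph.qrs_dur_mean_ms, morph.qrs_dur_sd_ms, morph.trunc_sd)
    qt_ms = _trunc_normal(rng, morph.qt_mean_ms, morph.qt_sd_ms, morph.trunc_sd)
    qt_ms = max(qt_ms, qrs_ms + 30.0)
    rr_ms = max(_trunc_normal(rng, morph.rr_mean_ms, morph.rr_sd_ms, morph.trunc_sd), MIN_RR_MS)

    d = int(round(qrs_ms * fs / 1000.0))
    onset = r_idx - int(round(morph.r_frac * d))
    j = onset + d
    t_end = min(onset + int(round(qt_ms * fs / 1000.0)), L - 2)
    if onset < 1 or j >= t_end:
        raise ValueError(f"degenerate beat geometry for class {label.name}")

    # heart mode (which experiment the beat "comes from"), then per-beat
    # multiplicative amplitude jitter, one factor per lead
    mode = morph.modes[int(rng.integers(len(morph.modes)))] if morph.modes else {}
    m_amp = mode.get("amp", 1.0)
    m_st = mode.get("st", 1.0)
    m_t = mode.get("t", 1.0)
    m_pol = mode.get("pol", 1)
    amp_fac = np.exp(rng.normal(0.0, morph.amp_jitter_frac, size=2)) if morph.amp_jitter_frac > 0 else np.ones(2)
    amp_fac = amp_fac * m_amp
    st_jit = rng.normal(0.0, morph.st_sd) if morph.st_sd > 0 else 0.0
    st_drawn = (m_st * morph.st_level[0] + st_jit, m_st * morph.st_level[1] + st_jit)

    n = np.arange(L, dtype=float)
    waveform = np.zeros((2, L))
    # T-wave support starts at least 25 ms after J so the ST measurement
    # point (J + 20 ms) carries the plateau level only
    t_on = j + max(25e-3 * fs, 0.2 * (t_end - j))
    for lead in range(2):
        a = amp_fac[lead]
        w = _bump(n, onset + 0.125 * d, 0.125 * d, a * m_pol * morph.q_amp[lead])
        w += _bump(n, onset + morph.r_frac * d, min(morph.r_frac, 1 - morph.r_frac) * d,
                   a * m_pol * morph.r_amp[lead])
        w += _bump(n, j - 0.125 * d, 0.125 * d, a * m_pol * morph.s_amp[lead])
        w += _bump(n, 0.5 * (t_on + t_end), 0.5 * (t_end - t_on), a * m_t * m_pol * morph.t_amp[lead])
        w += _st_plateau(n, float(j), float(t_end), st_drawn[lead], fs)
        waveform[lead] = w

    if config.noise_sd > 0:
        waveform = waveform + rng.normal(0.0, config.noise_sd, size=waveform.shape)
    if config.quantize_bits is not None:
        q = config.quantize_step_mv
        waveform = np.round(waveform / q) * q

    fid = Fiducials(qrs_onset=onset, r_peak=r_idx, j_point=j, t_end=t_end)
    params = {
        "qrs_dur_ms": d / fs * 1000.0,
        "qt_ms": (t_end - onset) / fs * 1000.0,
        "qrs_dur_drawn_ms": qrs_ms,
        "qt_drawn_ms": qt_ms,
        "rr_ms": rr_ms,
        "st_level_mv": st_drawn,
        "amp_factor": tuple(amp_fac),
        "mode": mode,
    }
    return SyntheticBeat(waveform=waveform, fiducials=fid, label=label,
                         rr_prev_ms=rr_ms, fs=fs, params=params)


def generate_dataset(
    counts: dict[BeatClass, int],
    config: GeneratorConfig,
    seed: int | None = None,
) -> list[SyntheticBeat]:
    """Generate a shuffled dataset with exactly ``counts[c]`` beats per class.

    Each beat draws from its own counter-derived substream of the root
    seed (``config.seed`` unless overridden), so the parameters of beat k
    of class c do not depend on how many beats of other classes were
    requested.
    """
    seed = config.seed if seed is None else seed
    beats: list[SyntheticBeat] = []
    for label in BeatClass:
        k = counts.get(label, 0)
        if k < 0:
            raise ValueError("counts must be non-negative")
        for i in range(k):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(int(label), i))
            beats.append(generate_beat(label, config, np.random.default_rng(child)))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
    order = shuffle_rng.permutation(len(beats))
    return [beats[i] for i in order]


def generate_record(
    beat_sequence: list[BeatClass],
    config: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
) -> SyntheticRecord:
    """Place a sequence of beats into a continuous two-lead record.

    R-R intervals are drawn from each beat's class distribution; a VPB is
    placed prematurely at ``prematurity_frac`` of the preceding interval.
    Baseline wander (a sinusoid at ``baseline_freq``) and white noise are
    added at record level.
    """
    if not beat_sequence:
        raise ValueError("beat sequence must be non-empty")
    rng = _as_rng(rng, config.seed)
    fs = config.fs
    beat_cfg = replace(config, noise_sd=0.0, baseline_amp=0.0)

    beats = [generate_beat(lab, beat_cfg, rng) for lab in beat_sequence]
    r_pos: list[int] = []
    pos = int(round(0.5 * fs))  # lead-in margin
    prev_rr = None
    for beat in beats:
        if prev_rr is None:
            rr = beat.rr_prev_ms
        elif beat.label is BeatClass.VPB and config.classes[beat.label].prematurity_frac:
            rr = max(config.classes[beat.label].prematurity_frac * prev_rr, MIN_RR_MS)
        else:
            rr = beat.rr_prev_ms
        if r_pos:
            pos = r_pos[-1] + int(round(rr * fs / 1000.0))
        r_pos.append(pos)
        prev_rr = rr if beat.label is not BeatClass.VPB else beat.rr_prev_ms

    L = config.window_samples
    r_in = config.r_index
    total = r_pos[-1] + L - r_in + int(round(0.5 * fs))
    signal = np.zeros((2, total))
    annotations = []
    for beat, rp in zip(beats, r_pos):
        start = rp - r_in
        signal[:, start:start + L] += beat.waveform
        annotations.append((rp, beat.label, beat.fiducials.shifted(start)))

    t = np.arange(total) / fs
    if config.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.baseline_amp * np.sin(2 * np.pi * config.baseline_freq * t + phase)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    return SyntheticRecord(signal=signal, fs=fs, annotations=annotations)
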