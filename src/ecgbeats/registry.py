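"""The fixed feature registry: the single source of truth for feature
names, order, family/subgroup membership, lead and units.

Four families are published:

* ``MorphD`` (71) — morphology from delineated landmarks: 7 both-lead
  interval/loop features plus 32 per lead (voltage, AUC, relative-AUC and
  positive-to-negative AUC-ratio features).
* ``MorphR`` (44) — morphology from the R position alone: 22 per lead
  (extrema value/position features and AUC families over <R-t, R+t>
  windows, t in {40, 60, 100} ms, and the full 280 ms window).
* ``SpectralD`` (24) — 12 per lead from the delineated QRS: 3 FFT band
  power sums, 3 spectrogram statistics, 4 wavelet-transform features,
  2 Wigner-Ville statistics.
* ``SpectralR`` (72) — the same 12-per-lead battery on <R-t, R+t>
  segments for t in {20, 30, 50} ms (subgroups S20/S30/S50).

Subgroups follow the study's subdivision: CommonD, LoopD, AreaD, AreaDa,
AreaDr, CommonR, AreaR, AreaRa, SpectralD, S20, S30, S50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synthetic import BeatClass

__all__ = [
    "FeatureRegistryEntry",
    "FeatureVector",
    "registry",
    "registry_names",
    "family_names",
    "subgroup_names",
    "export_registry_json",
    "RATIO_SENTINEL",
]

#: cap for positive-to-negative AUC ratios with a vanishing denominator
RATIO_SENTINEL = 1e6

LEADS = ("i", "ii")


@dataclass(frozen=True)
class FeatureRegistryEntry:
    name: str
    family: str      # MorphD | MorphR | SpectralD | SpectralR
    subgroup: str    # CommonD, LoopD, AreaD, ..., S20, S30, S50
    lead: str        # "i", "ii" or "both"
    units: str


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values for one beat."""

    values: dict[str, float]
    beat_id: int | None = None
    label: BeatClass | None = None

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def _morphd_entries() -> list[FeatureRegistryEntry]:
    E = FeatureRegistryEntry
    out = [
        E("qrs_d_ms", "MorphD", "CommonD", "both", "ms"),
        E("qt_ms", "MorphD", "CommonD", "both", "ms"),
        E("jtmax_ms", "MorphD", "CommonD", "both", "ms"),
        E("qrsloop_len_mv", "MorphD", "LoopD", "both", "mV"),
        E("qrsloop_angle_deg", "MorphD", "LoopD", "both", "deg"),
        E("sttloop_len_mv", "MorphD", "LoopD", "both", "mV"),
        E("sttloop_angle_deg", "MorphD", "LoopD", "both", "deg"),
    ]
    for lead in LEADS:
        out += [
            E(f"qrs_pos_amp_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"qrs_neg_amp_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"qrs_max_abs_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"t_amp_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"stt_maxdev_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"stt_maxdev_abs_{lead}", "MorphD", "CommonD", lead, "mV"),
            E(f"st20_{lead}", "MorphD", "CommonD", lead, "mV"),
        ]
        for interval in ("qrs", "stt", "qrst"):
            out += [
                E(f"auc_{interval}_{lead}", "MorphD", "AreaD", lead, "mV.s"),
                E(f"auc_{interval}_pos_{lead}", "MorphD", "AreaD", lead, "mV.s"),
                E(f"auc_{interval}_neg_{lead}", "MorphD", "AreaD", lead, "mV.s"),
                E(f"auc_{interval}_abs_{lead}", "MorphD", "AreaDa", lead, "mV.s"),
            ]
        # relative to the signed whole-QRS-T area (dimensionless)
        for rel in ("qrs", "qrs_pos", "qrs_neg", "qrs_abs",
                    "stt", "stt_pos", "stt_neg", "stt_abs",
                    "qrst_pos", "qrst_neg"):
            out.append(E(f"auc_{rel}_rel_{lead}", "MorphD", "AreaDr", lead, "1"))
        for interval in ("qrs", "stt", "qrst"):
            out.append(E(f"auc_{interval}_ratio_{lead}", "MorphD", "AreaDr", lead, "1"))
    return out


def _morphr_entries() -> list[FeatureRegistryEntry]:
    E = FeatureRegistryEntry
    out: list[FeatureRegistryEntry] = []
    for lead in LEADS:
        out += [
            E(f"r_max_{lead}", "MorphR", "CommonR", lead, "mV"),
            E(f"r_max_pos_{lead}", "MorphR", "CommonR", lead, "ms"),
            E(f"r_min_{lead}", "MorphR", "CommonR", lead, "mV"),
            E(f"r_min_pos_{lead}", "MorphR", "CommonR", lead, "ms"),
            E(f"r_range_{lead}", "MorphR", "CommonR", lead, "mV"),
            E(f"r_minmax_dt_{lead}", "MorphR", "CommonR", lead, "ms"),
        ]
        for t in (40, 60, 100):
            out.append(E(f"auc_r{t}_{lead}", "MorphR", "AreaR", lead, "mV.s"))
        out += [
            E(f"auc_rfull_{lead}", "MorphR", "AreaR", lead, "mV.s"),
            E(f"auc_rfull_pos_{lead}", "MorphR", "AreaR", lead, "mV.s"),
            E(f"auc_rfull_neg_{lead}", "MorphR", "AreaR", lead, "mV.s"),
        ]
        for t in (40, 60, 100):
            out.append(E(f"auc_r{t}_rel_{lead}", "MorphR", "AreaR", lead, "1"))
        for t in (40, 60, 100):
            out.append(E(f"absauc_r{t}_{lead}", "MorphR", "AreaRa", lead, "mV.s"))
        out.append(E(f"absauc_rfull_{lead}", "MorphR", "AreaRa", lead, "mV.s"))
        for t in (40, 60, 100):
            out.append(E(f"absauc_r{t}_rel_{lead}", "MorphR", "AreaRa", lead, "1"))
    return out


_SPECTRAL_BATTERY = (
    ("fft_0_35", "mV2"), ("fft_35_90", "mV2"), ("fft_125_250", "mV2"),
    ("stft_mean", "mV"), ("stft_median", "mV"), ("stft_max", "mV"),
    ("cwt_mean", "mV"), ("cwt_max", "mV"),
    ("cwt_corr_bestpos", "1"), ("cwt_corr_bestscale", "1"),
    ("wvd_max", "mV2"), ("wvd_mean", "mV2"),
)


def _spectral_entries(family: str, prefix: str, subgroup: str) -> list[FeatureRegistryEntry]:
    out = []
    for lead in LEADS:
        for stem, units in _SPECTRAL_BATTERY:
            out.append(FeatureRegistryEntry(f"{prefix}{stem}_{lead}", family, subgroup, lead, units))
    return out


def registry() -> list[FeatureRegistryEntry]:
    """The full, fixed-order feature registry (211 entries)."""
    out = _morphd_entries() + _morphr_entries()
    out += _spectral_entries("SpectralD", "d_", "SpectralD")
    for t in (20, 30, 50):
        out += _spectral_entries("SpectralR", f"s{t}_", f"S{t}")
    return out


def registry_names(family: str | None = None) -> list[str]:
    return [e.name for e in registry() if family is None or e.family == family]


def family_names() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for e in registry():
        out.setdefault(e.family, []).append(e.name)
    return out


def subgroup_names() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for e in registry():
        out.setdefault(e.subgroup, []).append(e.name)
    return out


def export_registry_json(path) -> None:
    entries = [e.__dict__ for e in registry()]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)
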