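"""End-to-end orchestration: simulate -> extract -> select -> benchmark.

The pipeline mirrors the study design: a labelled beat set (the
generator's ground-truth fiducials standing in for manual delineation),
the four feature families, per-family filter selection, subgroup
formation, and the nine-model cross-validated benchmark.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as _io
from .benchmark import BENCHMARK_MODELS, run_benchmark
from .morphology import extract_morphd, extract_morphr
from .registry import export_registry_json, family_names, subgroup_names
from .selection import filter_features
from .spectral import extract_spectrald, extract_spectralr
from .synthetic import BeatClass, GeneratorConfig, SyntheticBeat, default_config, generate_dataset

__all__ = ["RunConfig", "feature_matrix", "select_per_family", "run_pipeline",
           "DEFAULT_COUNTS"]

#: the study's class sizes: 220 NOR/ISM/ISE and the 172 available VPBs
DEFAULT_COUNTS: dict[BeatClass, int] = {
    BeatClass.NOR: 220, BeatClass.ISM: 220, BeatClass.ISE: 220, BeatClass.VPB: 172,
}

_FAMILIES = ("MorphD", "MorphR", "SpectralD", "SpectralR")


@dataclass(frozen=True)
class RunConfig:
    """Serializable pipeline configuration."""

    counts: dict[BeatClass, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    families: tuple[str, ...] = _FAMILIES
    alpha: float = 0.05
    folds: int = 10
    seed: int = 0
    out_dir: str = "ecgbeats_run"

    def to_dict(self) -> dict:
        return {
            "counts": {BeatClass(k).name: v for k, v in self.counts.items()},
            "families": list(self.families),
            "alpha": self.alpha, "folds": self.folds, "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        counts = {BeatClass[k]: int(v) for k, v in d["counts"].items()}
        return cls(counts=counts, families=tuple(d["families"]), alpha=float(d["alpha"]),
                   folds=int(d["folds"]), seed=int(d["seed"]), out_dir=d["out_dir"])


def feature_matrix(beats: list[SyntheticBeat], families: tuple[str, ...] = _FAMILIES) -> pd.DataFrame:
    """One row per beat: beat_id, label, then the requested families'
    features in registry order."""
    extractors = {
        "MorphD": extract_morphd, "MorphR": extract_morphr,
        "SpectralD": extract_spectrald, "SpectralR": extract_spectralr,
    }
    rows = []
    for i, beat in enumerate(beats):
        row: dict[str, float] = {"beat_id": i, "label": int(beat.label)}
        for fam in families:
            row.update(extractors[fam](beat, beat_id=i).values)
        rows.append(row)
    return pd.DataFrame(rows)


def select_per_family(
    df: pd.DataFrame, alpha: float = 0.05, families: tuple[str, ...] = _FAMILIES
) -> dict[str, list[str]]:
    """Filter selection run per feature family; returns retained names."""
    labels = df["label"].to_numpy()
    fam_names = family_names()
    retained: dict[str, list[str]] = {}
    for fam in families:
        cols = [c for c in fam_names[fam] if c in df.columns]
        res = filter_features(df[cols].to_numpy(float), labels, cols, alpha=alpha)
        retained[fam] = res.retained
    return retained


def _benchmark_groups(retained: dict[str, list[str]]) -> dict[str, list[str]]:
    """Whole retained families plus their subgroups, as benchmark rows."""
    sub = subgroup_names()
    groups: dict[str, list[str]] = {}
    for fam, cols in retained.items():
        if cols:
            groups[fam] = cols
        for sg, sg_cols in sub.items():
            inter = [c for c in cols if c in sg_cols]
            if inter and sg != fam:
                groups[sg] = inter
    return groups


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    gen_cfg: GeneratorConfig = default_config(seed=config.seed)
    beats = generate_dataset(config.counts, gen_cfg)
    manifest["stages"]["simulate"] = {
        "n_beats": len(beats),
        "per_class": {BeatClass(k).name: v for k, v in config.counts.items()},
    }

    df = feature_matrix(beats, config.families)
    feat_path = _io.write_features(df, out / "features.csv")
    export_registry_json(out / "registry.json")
    fam_sizes = {f: len(family_names()[f]) for f in config.families}
    manifest["stages"]["extract"] = {"families": fam_sizes, "table": feat_path.name}

    retained = select_per_family(df, alpha=config.alpha, families=config.families)
    (out / "selection.json").write_text(json.dumps(retained, indent=1))
    manifest["stages"]["select"] = {f: len(v) for f, v in retained.items()}

    groups = _benchmark_groups(retained)
    labels = df["label"].to_numpy()
    grid, reports = run_benchmark(groups, BENCHMARK_MODELS, df, labels,
                                  folds=config.folds, seed=config.seed)
    grid.to_csv(out / "accuracy_grid.csv", float_format="%.4f")

    perf_rows = []
    for (gname, mname), rep in reports.items():
        for ci, cname in enumerate(c.name for c in BeatClass):
            perf_rows.append({"group": gname, "model": mname, "class": cname,
                              "sensitivity": rep.sensitivity[ci],
                              "specificity": rep.specificity[ci],
                              "mean_accuracy": rep.mean_accuracy})
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False,
                                   float_format="%.4f")
    conf_frames = []
    for (gname, mname), rep in reports.items():
        cdf = pd.DataFrame(rep.confusion,
                           index=[c.name for c in BeatClass],
                           columns=[c.name for c in BeatClass])
        cdf.insert(0, "model", mname)
        cdf.insert(0, "group", gname)
        conf_frames.append(cdf)
    if conf_frames:
        pd.concat(conf_frames).to_csv(out / "confusion_matrices.csv")

    manifest["stages"]["benchmark"] = {
        "groups": {g: len(cols) for g, cols in groups.items()},
        "models": [m.name for m in BENCHMARK_MODELS],
        "grid": "accuracy_grid.csv",
    }
    manifest["hashes"] = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    _io.write_manifest(manifest, out / "manifest.json")
    return manifest
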