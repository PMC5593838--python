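"""File formats: delimited-text records with JSON annotation sidecars,
CSV feature tables with registry-ordered headers, and JSON manifests.

Sample indices in files are 0-based; record files carry time in seconds,
feature names carry ms.  Windows are half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import registry_names
from .synthetic import BeatClass, Fiducials, SyntheticRecord

__all__ = [
    "write_record",
    "read_record",
    "write_features",
    "read_features",
    "write_manifest",
    "read_manifest",
]


def write_record(record: SyntheticRecord, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (time_s, leadI_mV, leadII_mV) and
    ``<prefix>.annotations.json``."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    ann_path = prefix.with_suffix(".annotations.json")
    t = np.arange(record.signal.shape[1]) / record.fs
    df = pd.DataFrame({"time_s": t,
                       "leadI_mV": record.signal[0],
                       "leadII_mV": record.signal[1]})
    df.to_csv(csv_path, index=False, float_format="%.9g")
    ann = {
        "fs": record.fs,
        "annotations": [
            {"r_peak": int(r), "label": BeatClass(lab).name,
             "fiducials": {"qrs_onset": fid.qrs_onset, "r_peak": fid.r_peak,
                           "j_point": fid.j_point, "t_end": fid.t_end}}
            for r, lab, fid in record.annotations
        ],
    }
    ann_path.write_text(json.dumps(ann, indent=1))
    return csv_path, ann_path


def read_record(prefix: str | Path) -> SyntheticRecord:
    prefix = Path(prefix)
    csv_path = prefix if prefix.suffix == ".csv" else prefix.with_suffix(".csv")
    ann_path = csv_path.with_suffix("").with_suffix(".annotations.json")
    df = pd.read_csv(csv_path)
    expected = ["time_s", "leadI_mV", "leadII_mV"]
    if list(df.columns) != expected:
        raise ValueError(f"record header must be {expected}, got {list(df.columns)}")
    ann = json.loads(ann_path.read_text()) if ann_path.exists() else {"fs": None, "annotations": []}
    fs = ann["fs"]
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    annotations = [
        (a["r_peak"], BeatClass[a["label"]],
         Fiducials(**a["fiducials"]))
        for a in ann["annotations"]
    ]
    signal = np.vstack([df["leadI_mV"].to_numpy(), df["leadII_mV"].to_numpy()])
    return SyntheticRecord(signal=signal, fs=float(fs), annotations=annotations)


def write_features(df: pd.DataFrame, path: str | Path) -> Path:
    """Feature table: beat_id, label, then registry-ordered feature columns."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    known = set(registry_names()) | {"beat_id", "label"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown[:5]}")
    return df


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
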