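"""Interchange formats: EEG CSV + JSON sidecar, trial-table CSV, JSON reports.

An EEG recording is stored as a CSV with one row per time sample and one
column per channel (header = channel labels) next to a ``<stem>.json``
sidecar carrying the metadata the CSV cannot: sampling rate, state label
and provenance.  Reports are JSON with a schema version field, serialized
with sorted keys so identical results are byte-identical on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CHANNELS, EEGRecording

REPORT_SCHEMA_VERSION = "1.0"

TRIAL_COLUMNS = [
    "participant", "emotion", "psycap_score", "psycap_group",
    "RA", "RT1", "RS", "RT2",
    "sleep", "smoke", "alcohol", "trainings", "lectures",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_eeg_csv(rec: EEGRecording, path) -> Path:
    """Write samples as CSV (rows = time, columns = channels) + sidecar."""
    path = Path(path)
    frame = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
    frame.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "state_label": rec.state_label,
        "channel_labels": list(rec.channel_labels),
        **{k: v for k, v in rec.meta.items() if k in ("seed", "profile")},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_eeg_csv(path) -> EEGRecording:
    """Read a recording written by :func:`write_eeg_csv`.

    The header must be a subset of the canonical 14-channel label set; the
    sidecar JSON is mandatory (it holds the sampling rate).
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar for {path}: expected {sidecar_path}"
        )
    meta = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(path)
    unknown = [c for c in frame.columns if c not in CHANNELS]
    if unknown:
        raise ValueError(
            f"{path}, line 1: header contains non-channel columns {unknown}; "
            f"expected labels from {CHANNELS}"
        )
    return EEGRecording(
        samples=frame.values.T,
        fs=float(meta["fs"]),
        channel_labels=tuple(frame.columns),
        state_label=meta.get("state_label"),
        meta={k: meta[k] for k in ("seed", "profile") if k in meta},
    )


def write_trials_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trials_csv(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing trial-table columns {missing}")
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_report_json(report: dict, path) -> Path:
    """Deterministic JSON dump (schema-versioned, sorted keys)."""
    path = Path(path)
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **_jsonable(report)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
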