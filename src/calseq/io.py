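"""Reading and writing on-disk artifacts.

Formats
-------
traces
    HDF5 with datasets ``F`` (neurons x frames, float) and ``neuron_ids``,
    and attributes ``frame_rate_hz`` and ``block_id``.  A wide CSV matrix
    (header = neuron ids, one column per neuron) is accepted as a fallback
    for small fixtures; the frame rate must then be supplied by the caller.
trial table
    CSV with columns ``trial_id, session, trial_type, cue_onset_s,
    sound_onset_s, sound_offset_s, stim_onset_s, intensity_pct, delay_s``;
    absent events are empty cells.
results
    ``classification.csv`` (one row per neuron x session x window) plus
    ``metrics.json``; the simulator additionally writes
    ``ground_truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    FormatError,
    GroundTruth,
    Recording,
    TrialTable,
    TRIAL_COLUMNS,
    ValidationError,
    validate_classification,
)

__all__ = [
    "load_recording",
    "save_recording",
    "load_trial_table",
    "save_trial_table",
    "write_results",
    "load_results",
    "write_ground_truth",
    "load_ground_truth",
]


def save_recording(rec: Recording, path) -> Path:
    """Write a recording as HDF5 (or CSV if the suffix is ``.csv``)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(rec.fluorescence.T, columns=[str(i) for i in rec.neuron_ids])
        df.to_csv(path, index=False)
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=rec.fluorescence)
        ids = np.asarray(rec.neuron_ids)
        if ids.dtype.kind in "UO":
            ids = ids.astype("S")
        f.create_dataset("neuron_ids", data=ids)
        f.attrs["frame_rate_hz"] = float(rec.frame_rate)
        f.attrs["block_id"] = str(rec.block_id)
    return path


def load_recording(path, frame_rate: float | None = None) -> Recording:
    """Load fluorescence traces from HDF5 or the CSV fallback.

    Parameters
    ----------
    path
        ``.h5``/``.hdf5`` file in the traces format, or a wide ``.csv``
        matrix whose header row holds the neuron ids.
    frame_rate
        Required for CSV input, which carries no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        if frame_rate is None:
            raise FormatError("CSV traces carry no frame rate; pass frame_rate=")
        df = pd.read_csv(path)
        return _build_recording(
            df.to_numpy(dtype=float).T, frame_rate, np.asarray(df.columns), "block0"
        )
    with h5py.File(path, "r") as f:
        if "F" not in f:
            raise FormatError(f"{path}: missing dataset 'F'")
        if "frame_rate_hz" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'frame_rate_hz'")
        values = f["F"][()]
        rate = float(f.attrs["frame_rate_hz"])
        block = str(f.attrs.get("block_id", "block0"))
        if "neuron_ids" in f:
            ids = f["neuron_ids"][()]
            if ids.dtype.kind == "S":
                ids = ids.astype(str)
        else:
            ids = np.arange(values.shape[0])
    return _build_recording(values, rate, ids, block)


def _build_recording(values, rate, ids, block) -> Recording:
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        n, fr = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite trace value at neuron {ids[n]}, frame {fr}"
        )
    return Recording(values, rate, ids, block)


def save_trial_table(trials: TrialTable, path) -> Path:
    path = Path(path)
    trials.df.to_csv(path, index=False)
    return path


def load_trial_table(path) -> TrialTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: trial table missing columns {missing}")
    return TrialTable(df)


def write_results(records: pd.DataFrame, metrics: dict, out_dir) -> dict:
    """Write ``classification.csv`` and ``metrics.json`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    validate_classification(records)
    csv_path = out_dir / "classification.csv"
    records.to_csv(csv_path, index=False)
    json_path = out_dir / "metrics.json"
    json_path.write_text(json.dumps(_jsonify(metrics), indent=2, sort_keys=True))
    return {"classification": csv_path, "metrics": json_path}


def load_results(out_dir) -> tuple[pd.DataFrame, dict]:
    out_dir = Path(out_dir)
    records = pd.read_csv(out_dir / "classification.csv")
    for col in ("responsive", "selected", "insufficient"):
        records[col] = records[col].astype(bool)
    validate_classification(records)
    metrics = json.loads((out_dir / "metrics.json").read_text())
    return records, metrics


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "neurons": [
            {
                "neuron_id": _py(truth.neuron_ids[i]),
                "categories": sorted(truth.categories[i]),
                "amplitude": float(truth.amplitude[i]),
                "reliability": float(truth.reliability[i]),
            }
            for i in range(truth.n_neurons)
        ]
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_ground_truth(path) -> GroundTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    rows = payload["neurons"]
    return GroundTruth(
        neuron_ids=np.array([r["neuron_id"] for r in rows]),
        categories=[frozenset(r["categories"]) for r in rows],
        amplitude=np.array([r["amplitude"] for r in rows]),
        reliability=np.array([r["reliability"] for r in rows]),
    )


def _py(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return str(x) if isinstance(x, np.str_) else x


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    return obj
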