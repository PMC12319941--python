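"""File interfaces: BIDS-style events TSV, beta arrays with sidecar labels.

Events travel as tab-separated tables with columns (onset, duration,
trial_type, run, room_type). Beta arrays are saved as ``.npy`` with a
sidecar ``<name>.json`` recording dimension labels (subjects, runs,
condition ids, voxel count), so externally supplied run-level betas can
be fed into the decoding and contrast stages. An optional NIfTI export
writes a volumetric stand-in (voxels stacked along one axis) for viewers
that require it; nibabel is imported only when used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SCHEDULE_COLUMNS

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_beta_array",
    "read_beta_array",
    "write_table",
    "read_mask",
]


def write_events_tsv(schedule: pd.DataFrame, path) -> Path:
    path = Path(path)
    schedule.to_csv(path, sep="\t", index=False, columns=list(SCHEDULE_COLUMNS))
    return path


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} lacks required columns {missing}")
    if "run" not in df.columns:
        df["run"] = 0
    return df


def write_beta_array(values: np.ndarray, path, **labels) -> Path:
    """Save an array as .npy with a JSON sidecar of dimension labels."""
    path = Path(path)
    np.save(path, np.asarray(values))
    sidecar = path.with_suffix(".json")
    labels["shape"] = list(np.asarray(values).shape)
    sidecar.write_text(json.dumps(labels, indent=1, default=_jsonable))
    return path


def read_beta_array(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.load(path)
    sidecar = path.with_suffix(".json")
    labels = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, labels


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_mask(path) -> np.ndarray:
    """Voxel ids from a text list (one id per line) or a NIfTI label volume."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        return np.flatnonzero(vol.ravel() > 0)
    return np.loadtxt(path, dtype=int, ndmin=1)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
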