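"""On-disk dialects for recordings, feature tables, and evaluation reports.

A recording lives in two files: a data file (two-column CSV ``time_s,ppg``
or a NumPy ``.npz`` archive with a ``ppg`` array) plus a JSON sidecar
carrying ``subject_id``, ``fs``, and the reference cuff pressures. Feature
tables are plain CSV; evaluation reports are a single JSON document that
embeds the resolved configuration so a run can be reproduced from its
report alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "PlausibilityError",
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "write_features",
    "read_features",
    "write_report",
    "read_report",
]

# Physiological plausibility gate for reference (and predicted) pressures.
SBP_RANGE = (40.0, 260.0)
DBP_RANGE = (20.0, 160.0)


class PlausibilityError(ValueError):
    """Reference or predicted blood pressure outside the physiological gate."""


class RecordingFormatError(ValueError):
    """Malformed recording file or metadata sidecar."""


def check_bp_plausible(sbp: float, dbp: float) -> None:
    """Raise :class:`PlausibilityError` unless (sbp, dbp) is physiological.

    The gate is 40–260 mmHg systolic, 20–160 mmHg diastolic, with
    diastolic strictly below systolic.
    """
    if not (SBP_RANGE[0] <= sbp <= SBP_RANGE[1]):
        raise PlausibilityError(f"SBP {sbp} mmHg outside {SBP_RANGE}")
    if not (DBP_RANGE[0] <= dbp <= DBP_RANGE[1]):
        raise PlausibilityError(f"DBP {dbp} mmHg outside {DBP_RANGE}")
    if not dbp < sbp:
        raise PlausibilityError(f"DBP {dbp} must be strictly below SBP {sbp}")


@dataclass
class Recording:
    """One subject's raw PPG series with its reference cuff pressures.

    Parameters
    ----------
    subject_id : str
        Cohort-unique identifier.
    fs : float
        Sampling rate in Hz (100 Hz for the target hardware).
    samples : numpy.ndarray
        Ordered optical-amplitude series, arbitrary units.
    sbp_ref, dbp_ref : float
        Subject-level reference systolic / diastolic pressure in mmHg,
        shared by every window cut from this recording.
    """

    subject_id: str
    fs: float
    samples: np.ndarray
    sbp_ref: float
    dbp_ref: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D series")
        check_bp_plausible(self.sbp_ref, self.dbp_ref)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace(self, **changes: Any) -> "Recording":
        return dataclasses.replace(self, **changes)


def _meta_path_for(path: Path) -> Path:
    # recording.csv -> recording.meta.json
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix else path


def read_recording(path: str | Path, meta_path: str | Path | None = None) -> Recording:
    """Load a recording from ``path`` and its JSON sidecar.

    ``path`` may be a two-column CSV (``time_s, ppg``), a one-column CSV
    (``ppg``), or an ``.npz`` archive with a ``ppg`` array (optionally
    ``time_s``). When a time column is present, its median step is
    cross-checked against the sidecar ``fs`` to within 1%.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise RecordingFormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("subject_id", "fs", "sbp_ref", "dbp_ref"):
        if key not in meta:
            raise RecordingFormatError(f"sidecar {meta_path} missing field {key!r}")
    fs = float(meta["fs"])

    time_s: np.ndarray | None = None
    if path.suffix == ".npz":
        with np.load(path) as arc:
            if "ppg" not in arc:
                raise RecordingFormatError(f"{path} has no 'ppg' array")
            samples = np.asarray(arc["ppg"], dtype=float)
            if "time_s" in arc:
                time_s = np.asarray(arc["time_s"], dtype=float)
    else:
        frame = pd.read_csv(path)
        if frame.columns.duplicated().any():
            raise RecordingFormatError(f"{path} has duplicate columns")
        if "ppg" not in frame.columns:
            raise RecordingFormatError(f"{path} has no 'ppg' column")
        samples = frame["ppg"].to_numpy(dtype=float)
        if "time_s" in frame.columns:
            time_s = frame["time_s"].to_numpy(dtype=float)

    if time_s is not None and time_s.size >= 2:
        dt = float(np.median(np.diff(time_s)))
        if dt <= 0:
            raise RecordingFormatError(f"{path}: non-increasing time column")
        fs_obs = 1.0 / dt
        if abs(fs_obs - fs) > 0.01 * fs:
            raise RecordingFormatError(
                f"{path}: time column implies fs={fs_obs:.3f} Hz, "
                f"sidecar says {fs} Hz (>1% mismatch)"
            )

    return Recording(
        subject_id=str(meta["subject_id"]),
        fs=fs,
        samples=samples,
        sbp_ref=float(meta["sbp_ref"]),
        dbp_ref=float(meta["dbp_ref"]),
    )


def write_recording(rec: Recording, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a recording as CSV (or ``.npz``) plus JSON sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else path.with_suffix(".meta.json")
    t = np.arange(rec.samples.size) / rec.fs
    if path.suffix == ".npz":
        np.savez_compressed(path, time_s=t, ppg=rec.samples)
    else:
        pd.DataFrame({"time_s": t, "ppg": rec.samples}).to_csv(
            path, index=False, float_format="%.10g"
        )
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "sbp_ref": rec.sbp_ref,
        "dbp_ref": rec.dbp_ref,
        "n_samples": int(rec.samples.size),
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def write_features(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (one row per retained lag-matrix row) as CSV."""
    pd.DataFrame(frame).to_csv(Path(path), index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(report: Any, path: str | Path) -> None:
    """Serialize an evaluation report (metrics, per-subject predictions,
    fold assignments, resolved config) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
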