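"""Readers and writers for signals, ground-truth sidecars and feature tables.

Interchange format is plain CSV: signals as two columns (time_s, amplitude)
or a single amplitude column with the sampling rate supplied out of band;
feature tables carry the canonical 78 feature columns plus subject_id, age
and n_beats.  A WFDB-style record can be read if the optional ``wfdb``
package is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import RawRecording
from .features import FEATURE_NAMES

__all__ = [
    "read_signal",
    "write_signal",
    "read_wfdb",
    "write_ground_truth",
    "read_ground_truth",
    "write_feature_table",
    "read_feature_table",
]


def write_signal(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as two-column CSV (time_s, amplitude)."""
    df = pd.DataFrame({"time_s": rec.times, "amplitude": rec.samples})
    df.to_csv(path, index=False, float_format="%.10g")


def read_signal(
    path: str | Path,
    fs_hint: float | None = None,
    subject_id: str | None = None,
    age: float | None = None,
) -> RawRecording:
    """Read a signal CSV back into a :class:`RawRecording`.

    Two-column files (time_s, amplitude) have the sampling rate inferred
    from the median time step, with uniformity enforced (max jitter < 1%
    of the step); single-column files require ``fs_hint``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "amplitude" not in df.columns:
        if df.shape[1] == 1:
            df.columns = ["amplitude"]
        elif df.shape[1] == 2:
            df.columns = ["time_s", "amplitude"]
        else:
            raise ValueError(f"cannot interpret columns {list(df.columns)} in {path}")
    x = df["amplitude"].to_numpy(dtype=float)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time column is not strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 0.01 * step:
            raise ValueError("non-uniform sampling: time-step jitter exceeds 1%")
        fs = 1.0 / step
    else:
        if fs_hint is None:
            raise ValueError("single-column signal needs fs_hint (sampling rate)")
        fs = float(fs_hint)
    return RawRecording(samples=x, fs=fs, subject_id=subject_id, age=age)


def read_wfdb(record_path: str | Path, channel: int = 0) -> RawRecording:
    """Read one channel of a WFDB record, if the optional ``wfdb`` package
    is installed (physiologic-database conventions; CSV remains the
    package's native interchange format)."""
    try:
        import wfdb  # optional dependency
    except ImportError as err:
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); CSV signals need no extra dependency"
        ) from err
    record = wfdb.rdrecord(str(record_path))
    sig = np.asarray(record.p_signal)[:, channel]
    return RawRecording(samples=sig, fs=float(record.fs), subject_id=record.record_name)


_GT_COLUMNS = [
    "subject_id", "beat_index", "onset_s",
    "a_inc", "mu_inc", "sigma_inc", "a_ref", "mu_ref", "sigma_ref",
]


def write_ground_truth(beats: pd.DataFrame, subject_id: str, path: str | Path) -> None:
    """Write the simulator's per-beat ground truth sidecar table."""
    out = beats.copy()
    out["subject_id"] = subject_id
    out[_GT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-subject feature table (canonical column order enforced)."""
    meta = [c for c in ("subject_id", "age", "n_beats") if c in table.columns]
    cols = meta + [c for c in FEATURE_NAMES if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing {len(missing)} canonical columns")
    return df
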