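"""Documented text formats.

Raw CSV: header ``timestamp_iso8601,x_g,y_g,z_g``, one row per sample,
local civil time. Epoch CSV: ``timestamp,enmo_g,wear,sleep``. Daily CSV:
one row per subject-day with every day-summary field. Subjects CSV:
``subject_id,group,age,sex,vo2peak``.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from wristpa.errors import InputError
from wristpa.raw import EpochSeries, RawRecording

RAW_COLUMNS = ["timestamp_iso8601", "x_g", "y_g", "z_g"]
SUBJECT_COLUMNS = ["subject_id", "group", "age", "sex", "vo2peak"]


def write_raw_csv(rec: RawRecording, path) -> None:
    ts = pd.date_range(
        rec.start_time, periods=rec.n_samples, freq=pd.Timedelta(seconds=1.0 / rec.fs)
    )
    df = pd.DataFrame(
        {
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_g": rec.x,
            "y_g": rec.y,
            "z_g": rec.z,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_raw_csv(path, fs: float, device_id: str | None = None) -> RawRecording:
    """Read a raw CSV. The sampling rate is taken from configuration; only
    the first timestamp is parsed (rows are contract-defined equidistant)."""
    df = pd.read_csv(path, dtype={"timestamp_iso8601": str})
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: raw CSV lacks column(s) {missing}")
    if df.empty:
        raise InputError(f"{path}: empty raw CSV")
    start = datetime.fromisoformat(df["timestamp_iso8601"].iloc[0])
    return RawRecording(
        start_time=start,
        fs=fs,
        x=df["x_g"].to_numpy(float),
        y=df["y_g"].to_numpy(float),
        z=df["z_g"].to_numpy(float),
        device_id=device_id or Path(path).stem,
    )


def write_epoch_csv(epochs: EpochSeries, path) -> None:
    epochs.to_frame().to_csv(path, index=False, float_format="%.8f")


def read_epoch_csv(path) -> EpochSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in ("timestamp", "enmo_g", "wear"):
        if col not in df.columns:
            raise InputError(f"{path}: epoch CSV lacks column {col!r}")
    if len(df) < 2:
        raise InputError(f"{path}: epoch CSV needs at least 2 rows")
    step = (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds()
    return EpochSeries(
        start_time=df["timestamp"].iloc[0].to_pydatetime(),
        epoch_length=step,
        enmo=df["enmo_g"].to_numpy(float),
        wear=df["wear"].to_numpy(bool),
        sleep=df["sleep"].to_numpy(bool) if "sleep" in df.columns else None,
    )


def write_subjects_csv(subjects: pd.DataFrame, path) -> None:
    subjects[SUBJECT_COLUMNS].to_csv(path, index=False, float_format="%.4f")


def read_subjects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: subjects CSV lacks column(s) {missing}")
    return df


def write_daily_csv(days: pd.DataFrame, path) -> None:
    days.to_csv(path, index=False, float_format="%.6f")


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise InputError(f"{path}: daily CSV lacks column 'subject_id'")
    return df


def stable_checksum(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
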