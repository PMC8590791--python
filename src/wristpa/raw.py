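"""Raw triaxial signal processing.

Converts raw acceleration (gravitational units, fixed sampling rate) into a
wear-flagged ENMO epoch series: per-sample ENMO with negative truncation,
fixed-length epoch averaging, sliding-window non-wear detection from
per-axis standard deviation and range, and a simplified offset/gain
calibration against local gravity. Also houses the 30-s rolling-mean rule
for peak oxygen uptake from cardiopulmonary exercise testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from wristpa.errors import ConfigError, InputError

__all__ = [
    "RawRecording",
    "EpochSeries",
    "CalibrationReport",
    "enmo_sample",
    "enmo",
    "epoch_aggregate",
    "detect_nonwear",
    "simple_calibrate",
    "peak_vo2",
]


@dataclass
class RawRecording:
    """A continuous triaxial recording in gravitational units (g)."""

    start_time: datetime
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    device_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (isinstance(self.fs, (int, float)) and math.isfinite(self.fs) and self.fs > 0):
            raise InputError(f"sampling rate must be a positive number, got {self.fs!r}")
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InputError("axis arrays must have equal length")
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if a.size and not np.all(np.isfinite(a)):
                raise InputError(f"non-finite values in axis {name}")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def axes(self) -> np.ndarray:
        """Samples as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class EpochSeries:
    """Per-epoch ENMO values with wear (and optional sleep) flags.

    Epochs are half-open intervals [t, t + epoch_length) aligned to
    ``start_time``; ``enmo`` is non-negative everywhere.
    """

    start_time: datetime
    epoch_length: float
    enmo: np.ndarray
    wear: np.ndarray = None
    sleep: np.ndarray | None = None

    def __post_init__(self):
        self.enmo = np.asarray(self.enmo, dtype=float)
        if np.any(self.enmo < 0):
            raise InputError("epoch ENMO must be non-negative")
        if self.wear is None:
            self.wear = np.ones(len(self.enmo), dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        if len(self.wear) != len(self.enmo):
            raise InputError("wear flags must match epoch count")
        if self.sleep is not None:
            self.sleep = np.asarray(self.sleep, dtype=bool)
            if len(self.sleep) != len(self.enmo):
                raise InputError("sleep flags must match epoch count")

    def __len__(self) -> int:
        return len(self.enmo)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self.enmo),
            freq=pd.Timedelta(seconds=self.epoch_length),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"timestamp": self.timestamps(), "enmo_g": self.enmo, "wear": self.wear}
        )
        df["sleep"] = self.sleep if self.sleep is not None else False
        return df

    def slice(self, i: int, j: int) -> "EpochSeries":
        return EpochSeries(
            start_time=self.start_time + timedelta(seconds=i * self.epoch_length),
            epoch_length=self.epoch_length,
            enmo=self.enmo[i:j],
            wear=self.wear[i:j],
            sleep=None if self.sleep is None else self.sleep[i:j],
        )


@dataclass
class CalibrationReport:
    """Per-axis offset/gain fit from static (low-variance) windows."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    n_static_windows: int = 0
    applied: bool = False

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.applied and np.any(self.gain <= 0):
            raise InputError("calibration gains must be positive")


def enmo_sample(x: float, y: float, z: float) -> float:
    """Euclidean norm of (x, y, z) minus one, truncated at zero.

    Gravity-corrected activity magnitude for a single sample; negative
    values (norm below 1 g) are rounded to zero.
    """
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise InputError("non-finite acceleration sample")
    return max(math.sqrt(x * x + y * y + z * z) - 1.0, 0.0)


def enmo(xyz: np.ndarray) -> np.ndarray:
    """Vectorized per-sample ENMO for an (n, 3) array."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.size and not np.all(np.isfinite(xyz)):
        raise InputError("non-finite acceleration sample")
    return np.maximum(np.linalg.norm(xyz, axis=-1) - 1.0, 0.0)


def epoch_aggregate(
    rec: RawRecording,
    epoch_length: float = 5.0,
    truncate: str = "sample",
) -> EpochSeries:
    """Average per-sample ENMO over fixed epochs.

    ``truncate`` selects when negatives are zeroed: ``"sample"`` (default)
    truncates each sample before averaging; ``"epoch"`` averages the signed
    norm-minus-one and truncates the epoch mean. Trailing samples that do
    not fill a whole epoch are dropped.
    """
    if truncate not in ("sample", "epoch"):
        raise ConfigError(f"unknown truncation mode {truncate!r}")
    spe = int(round(rec.fs * epoch_length))
    if rec.n_samples == 0:
        raise InputError("empty recording")
    if rec.n_samples < spe:
        raise InputError(
            f"recording has {rec.n_samples} samples, fewer than one "
            f"{epoch_length}-s epoch at {rec.fs} Hz"
        )
    n_epochs = rec.n_samples // spe
    norm1 = np.linalg.norm(rec.axes(), axis=1) - 1.0
    if truncate == "sample":
        per_sample = np.maximum(norm1, 0.0)
        vals = per_sample[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1)
    else:
        vals = norm1[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1)
        vals = np.maximum(vals, 0.0)
    return EpochSeries(start_time=rec.start_time, epoch_length=epoch_length, enmo=vals)


def detect_nonwear(
    rec: RawRecording,
    epoch_length: float = 5.0,
    window_min: float = 60.0,
    step_min: float = 15.0,
    sd_thresh: float = 0.013,
    range_thresh: float = 0.050,
    min_axes: int = 2,
) -> np.ndarray:
    """Flag non-wear epochs from long-window per-axis variability.

    A sliding window (``window_min`` minutes, advancing by ``step_min``)
    is non-wear when at least ``min_axes`` axes have per-axis SD below
    ``sd_thresh`` OR per-axis value range below ``range_thresh`` (strict
    inequalities). An epoch is non-wear if any covering window is
    non-wear. Returns a boolean non-wear mask aligned to the epoch grid of
    ``epoch_aggregate``.
    """
    if window_min < step_min:
        raise ConfigError("non-wear window must be at least one step long")
    win = int(round(window_min * 60 * rec.fs))
    step = int(round(step_min * 60 * rec.fs))
    n = rec.n_samples
    if n < win:
        raise InputError("recording shorter than one non-wear window")
    axes = rec.axes()
    sample_nonwear = np.zeros(n, dtype=bool)
    starts = list(range(0, n - win + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)  # cover the trailing tail
    for s in starts:
        block = axes[s : s + win]
        sd = block.std(axis=0)
        rng = block.max(axis=0) - block.min(axis=0)
        hits = int(np.sum((sd < sd_thresh) | (rng < range_thresh)))
        if hits >= min_axes:
            sample_nonwear[s : s + win] = True
    spe = int(round(rec.fs * epoch_length))
    n_epochs = n // spe
    per_epoch = sample_nonwear[: n_epochs * spe].reshape(n_epochs, spe)
    return per_epoch.any(axis=1)


def _static_window_means(
    axes: np.ndarray, win: int, sd_thresh: float
) -> np.ndarray:
    """Means of non-overlapping windows whose every axis SD is below threshold."""
    n_win = len(axes) // win
    means = []
    for i in range(n_win):
        block = axes[i * win : (i + 1) * win]
        if np.all(block.std(axis=0) < sd_thresh):
            means.append(block.mean(axis=0))
    return np.array(means) if means else np.empty((0, 3))


def simple_calibrate(
    rec: RawRecording,
    static_window_s: float = 10.0,
    sd_thresh: float = 0.013,
    min_windows: int = 10,
    min_spread: float = 0.05,
    n_iter: int = 25,
) -> tuple[RawRecording, CalibrationReport]:
    """Fit per-axis offset and gain so static-window norms approach 1 g.

    Static windows are non-overlapping ``static_window_s`` spans with all
    per-axis SDs below ``sd_thresh``; their mean vectors should lie on the
    unit sphere. Iteratively reweighted least squares maps each axis as
    ``calibrated = gain * raw + offset``. Degrades gracefully: with fewer
    than ``min_windows`` static windows, or insufficient orientation
    spread, the recording is returned unchanged with ``applied=False``.
    """
    axes = rec.axes()
    win = int(round(static_window_s * rec.fs))
    if win < 2 or len(axes) < win:
        return rec, CalibrationReport(applied=False)
    pts = _static_window_means(axes, win, sd_thresh)
    report = CalibrationReport(n_static_windows=len(pts), applied=False)
    if len(pts) < min_windows:
        return rec, report
    # need >= 2 distinct orientations for gain+offset to be identifiable
    spread = pts.max(axis=0) - pts.min(axis=0)
    if np.max(spread) < min_spread:
        return rec, report
    gain = np.ones(3)
    offset = np.zeros(3)
    for _ in range(n_iter):
        cal = pts * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        norms[norms == 0] = 1.0
        target = cal / norms[:, None]  # closest points on the unit sphere
        for k in range(3):
            A = np.column_stack([pts[:, k], np.ones(len(pts))])
            coef, *_ = np.linalg.lstsq(A, target[:, k], rcond=None)
            gain[k], offset[k] = coef
    if np.any(gain <= 0) or not np.all(np.isfinite(gain)) or not np.all(np.isfinite(offset)):
        return rec, report
    calibrated = replace(
        rec,
        x=rec.x * gain[0] + offset[0],
        y=rec.y * gain[1] + offset[1],
        z=rec.z * gain[2] + offset[2],
    )
    report.gain = gain
    report.offset = offset
    report.applied = True
    return calibrated, report


def peak_vo2(vo2_series) -> float:
    """Peak oxygen uptake: maximum 30-s rolling mean of a 10-s-interval
    VO2 series, i.e. the highest mean of three consecutive values."""
    v = np.asarray(vo2_series, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise InputError("VO2 series must contain at least 3 values")
    if not np.all(np.isfinite(v)):
        raise InputError("non-finite VO2 value")
    rolling = np.convolve(v, np.ones(3) / 3.0, mode="valid")
    return float(rolling.max())
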