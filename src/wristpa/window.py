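"""Most-active 10-hour window of a day and the distribution of its midpoints."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as date_t, datetime, time, timedelta

import numpy as np
import pandas as pd

from wristpa.classify import CutoffScheme
from wristpa.errors import ConfigError, InputError
from wristpa.raw import EpochSeries

__all__ = ["WindowResult", "most_active_window", "midpoint_histogram"]


@dataclass(frozen=True)
class WindowResult:
    date: date_t
    window_start: time
    window_length_h: float
    midpoint: time
    window_activity: float


def _clock(seconds: float) -> time:
    return (datetime(2000, 1, 1) + timedelta(seconds=seconds % 86400)).time()


def most_active_window(
    epochs: EpochSeries,
    length_h: float = 10.0,
    metric: str = "tpa_minutes",
    scheme: CutoffScheme = CutoffScheme(),
    wrap: bool = False,
) -> WindowResult:
    """Contiguous window of ``length_h`` hours maximizing daily activity.

    ``metric="tpa_minutes"`` counts wear epochs at or above the light
    cut-off (TPA minutes in-window); ``"enmo_sum"`` sums wear-epoch ENMO.
    Candidate windows slide by one epoch; ties break to the earliest start.
    Windows stay within the civil day unless ``wrap`` is set.
    """
    if length_h >= 24:
        raise ConfigError("window length must be below 24 h")
    if metric not in ("tpa_minutes", "enmo_sum"):
        raise ConfigError(f"unknown window metric {metric!r}")
    n = len(epochs)
    epoch_min = epochs.epoch_length / 60.0
    win = int(round(length_h * 3600 / epochs.epoch_length))
    expected = int(round(86400 / epochs.epoch_length))
    if n != expected:
        raise InputError(
            f"day must have full epoch coverage ({expected} epochs), got {n}"
        )
    if metric == "tpa_minutes":
        score = (epochs.wear & (epochs.enmo >= scheme.light)).astype(float) * epoch_min
    else:
        score = np.where(epochs.wear, epochs.enmo, 0.0)
    if wrap:
        score = np.concatenate([score, score[: win - 1]])
    csum = np.concatenate([[0.0], np.cumsum(score)])
    sums = csum[win:] - csum[: len(csum) - win]
    best = int(np.argmax(sums))  # argmax returns the first maximum -> earliest
    start_s = best * epochs.epoch_length
    mid_s = start_s + length_h * 1800  # + half the window, in seconds
    return WindowResult(
        date=epochs.start_time.date(),
        window_start=_clock(start_s),
        window_length_h=length_h,
        midpoint=_clock(mid_s),
        window_activity=float(sums[best]),
    )


def midpoint_histogram(
    results,
    bin_min: float = 30.0,
) -> pd.Series:
    """Counts of window midpoints in half-open clock-time bins [t, t+bin).

    Accepts :class:`WindowResult` objects or plain ``datetime.time``
    values; returns a Series indexed by bin start time covering 24 h.
    """
    n_bins = int(np.ceil(24 * 60 / bin_min))
    edges = [_clock(i * bin_min * 60) for i in range(n_bins)]
    counts = np.zeros(n_bins, dtype=int)
    for r in results:
        t = r.midpoint if isinstance(r, WindowResult) else r
        seconds = t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6
        counts[int(seconds // (bin_min * 60))] += 1
    return pd.Series(counts, index=pd.Index(edges, name="bin_start"), name="count")
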