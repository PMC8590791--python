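"""Per-day intensity classification, bout detection, calendar features and
validity decisions.

Intensity classes follow acceleration cut-offs anchored to MET levels:
sedentary below the light cut-off, then LPA / MPA / VPA with boundaries
inclusive upward. A day is valid at >= 600 wear minutes; a subject is
included when each of the two measurement weeks has at least four valid
weekdays and one valid weekend day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as date_t, time, timedelta
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from wristpa.errors import DayOutOfRangeError, InputError
from wristpa.raw import EpochSeries

__all__ = [
    "CutoffScheme",
    "DaySummary",
    "SubjectValidity",
    "CalendarFeatures",
    "classify_epoch",
    "classify_epochs",
    "summarize_day",
    "bouted_mvpa",
    "calendar_features",
    "subject_validity",
    "sleep_minutes",
    "split_days",
    "season_of",
    "N_ANALYSIS_DAYS",
    "MIN_WEAR_MINUTES",
]

logger = logging.getLogger(__name__)

#: analyzable measurement days (day 14 lacks a closing midnight)
N_ANALYSIS_DAYS = 13
#: valid-day wear-time threshold, minutes (>= 10 h)
MIN_WEAR_MINUTES = 600.0

CLASSES = ("sedentary", "lpa", "mpa", "vpa")

_SEASONS = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
}

_DOW = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


@dataclass(frozen=True)
class CutoffScheme:
    """Acceleration cut-offs (g) with their MET anchors."""

    light: float = 0.03
    moderate: float = 0.1
    vigorous: float = 0.4
    met_anchors: dict = field(
        default_factory=lambda: {"light": 2.0, "moderate": 3.0, "vigorous": 6.0}
    )

    def __post_init__(self):
        if not (0 < self.light < self.moderate < self.vigorous):
            raise InputError(
                "cut-offs must satisfy 0 < light < moderate < vigorous, got "
                f"{self.light}/{self.moderate}/{self.vigorous}"
            )


class CalendarFeatures(NamedTuple):
    day_of_week: str
    is_weekend: bool
    measurement_day: int
    week_index: int
    season: str


@dataclass
class DaySummary:
    """One calendar day of one subject, at epoch resolution."""

    subject_id: str
    date: date_t
    day_of_week: str
    is_weekend: bool
    measurement_day: int
    week_index: int
    season: str
    wear_minutes: float
    sedentary_minutes: float
    lpa_minutes: float
    mpa_minutes: float
    vpa_minutes: float
    bouted_mvpa_minutes: float
    sleep_minutes: float | None = None
    window_midpoint: time | None = None

    @property
    def mvpa_minutes(self) -> float:
        return self.mpa_minutes + self.vpa_minutes

    @property
    def tpa_minutes(self) -> float:
        return self.lpa_minutes + self.mpa_minutes + self.vpa_minutes

    @property
    def valid(self) -> bool:
        return self.wear_minutes >= MIN_WEAR_MINUTES

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "date": self.date.isoformat(),
            "day_of_week": self.day_of_week,
            "is_weekend": self.is_weekend,
            "measurement_day": self.measurement_day,
            "week_index": self.week_index,
            "season": self.season,
            "wear_minutes": self.wear_minutes,
            "sedentary_minutes": self.sedentary_minutes,
            "lpa_minutes": self.lpa_minutes,
            "mpa_minutes": self.mpa_minutes,
            "vpa_minutes": self.vpa_minutes,
            "mvpa_minutes": self.mvpa_minutes,
            "tpa_minutes": self.tpa_minutes,
            "bouted_mvpa_minutes": self.bouted_mvpa_minutes,
            "sleep_minutes": self.sleep_minutes,
            "valid": self.valid,
            "window_midpoint": (
                self.window_midpoint.isoformat() if self.window_midpoint else None
            ),
        }


@dataclass
class SubjectValidity:
    """Per-week valid-day counts and the inclusion decision."""

    subject_id: str
    week1_valid_weekdays: int
    week1_valid_weekend_days: int
    week2_valid_weekdays: int
    week2_valid_weekend_days: int

    @property
    def included(self) -> bool:
        return (
            self.week1_valid_weekdays >= 4
            and self.week1_valid_weekend_days >= 1
            and self.week2_valid_weekdays >= 4
            and self.week2_valid_weekend_days >= 1
        )


def classify_epoch(enmo: float, scheme: CutoffScheme = CutoffScheme()) -> str:
    """Intensity class of one epoch ENMO value (boundaries inclusive upward)."""
    if enmo < 0:
        raise InputError(f"negative ENMO {enmo}")
    if enmo < scheme.light:
        return "sedentary"
    if enmo < scheme.moderate:
        return "lpa"
    if enmo < scheme.vigorous:
        return "mpa"
    return "vpa"


def classify_epochs(
    enmo: np.ndarray, scheme: CutoffScheme = CutoffScheme()
) -> np.ndarray:
    """Vectorized :func:`classify_epoch`; returns class labels."""
    enmo = np.asarray(enmo, dtype=float)
    if np.any(enmo < 0):
        raise InputError("negative ENMO value")
    idx = np.digitize(enmo, [scheme.light, scheme.moderate, scheme.vigorous])
    return np.array(CLASSES)[idx]


def season_of(d: date_t) -> str:
    return _SEASONS[d.month]


def calendar_features(date: date_t, recording_start: date_t) -> CalendarFeatures:
    """Calendar covariates for one measurement day.

    Day 1 is ``recording_start`` (the first midnight after device receipt);
    only days 1-13 are analyzable, week 1 spans days 1-7 and week 2 days
    8-13. Dates outside that range raise :class:`DayOutOfRangeError`.
    """
    mday = (date - recording_start).days + 1
    if not 1 <= mday <= N_ANALYSIS_DAYS:
        raise DayOutOfRangeError(date, mday)
    dow = _DOW[date.weekday()]
    return CalendarFeatures(
        day_of_week=dow,
        is_weekend=date.weekday() >= 5,
        measurement_day=mday,
        week_index=1 if mday <= 7 else 2,
        season=season_of(date),
    )


def _check_one_day(epochs: EpochSeries) -> date_t:
    ts = epochs.timestamps()
    end = ts[-1] + pd.Timedelta(seconds=epochs.epoch_length)
    day = ts[0].date()
    if (end - pd.Timestamp(day)) > pd.Timedelta(days=1):
        raise InputError("epochs span a civil midnight; summarize one day at a time")
    return day


def summarize_day(
    epochs: EpochSeries,
    scheme: CutoffScheme = CutoffScheme(),
    subject_id: str = "",
    recording_start: date_t | None = None,
    min_bout_min: float = 10.0,
) -> DaySummary:
    """Summarize one civil day of epochs into class minutes and validity.

    Non-wear epochs contribute to no class, so sedentary + LPA + MPA + VPA
    equals wear minutes exactly at epoch resolution.
    """
    day = _check_one_day(epochs)
    if recording_start is None:
        recording_start = day
    feats = calendar_features(day, recording_start)
    wear = epochs.wear
    labels = classify_epochs(epochs.enmo, scheme)
    minutes = {
        c: float(np.sum(wear & (labels == c))) * epochs.epoch_length / 60.0
        for c in CLASSES
    }
    # wear minutes as the sum of class minutes keeps the partition exact
    # in floating point (count*(e/60) terms need not sum to total*(e/60))
    wear_minutes = sum(minutes[c] for c in CLASSES)
    return DaySummary(
        subject_id=subject_id,
        date=day,
        day_of_week=feats.day_of_week,
        is_weekend=feats.is_weekend,
        measurement_day=feats.measurement_day,
        week_index=feats.week_index,
        season=feats.season,
        wear_minutes=wear_minutes,
        sedentary_minutes=minutes["sedentary"],
        lpa_minutes=minutes["lpa"],
        mpa_minutes=minutes["mpa"],
        vpa_minutes=minutes["vpa"],
        bouted_mvpa_minutes=bouted_mvpa(epochs, scheme, min_bout_min),
        sleep_minutes=sleep_minutes(epochs),
    )


def bouted_mvpa(
    epochs: EpochSeries,
    scheme: CutoffScheme = CutoffScheme(),
    min_bout_min: float = 10.0,
    tolerance_epochs: int = 0,
) -> float:
    """Minutes of MVPA accumulated in runs of at least ``min_bout_min``
    consecutive minutes.

    A run is a maximal stretch of wear epochs at or above the moderate
    cut-off; any sub-threshold or non-wear epoch breaks it (strict reading
    of "consecutive"; ``tolerance_epochs`` > 0 allows that many
    interrupting epochs per gap without ending the run).
    """
    active = epochs.wear & (epochs.enmo >= scheme.moderate)
    epoch_min = epochs.epoch_length / 60.0
    min_run = int(np.ceil(min_bout_min / epoch_min))
    total = 0
    run = 0
    gap = 0
    for a in active:
        if a:
            run += 1
            gap = 0
        else:
            gap += 1
            if gap > tolerance_epochs:
                if run >= min_run:
                    total += run
                run = 0
                gap = 0
    if run >= min_run:
        total += run
    return total * epochs.epoch_length / 60.0


def sleep_minutes(epochs: EpochSeries) -> float | None:
    """Sum of flagged sleep epochs, in minutes; None when unannotated."""
    if epochs.sleep is None:
        logger.debug("sleep annotation absent; sleep minutes unavailable")
        return None
    return float(np.sum(epochs.sleep)) * epochs.epoch_length / 60.0


def subject_validity(days: Sequence[DaySummary]) -> SubjectValidity:
    """Inclusion decision: each week needs >= 4 valid weekdays and >= 1
    valid weekend day. Depends only on (valid, is_weekend, week_index)."""
    subject_ids = {d.subject_id for d in days}
    if len(subject_ids) > 1:
        raise InputError(f"days belong to multiple subjects: {sorted(subject_ids)}")
    counts = {(1, False): 0, (1, True): 0, (2, False): 0, (2, True): 0}
    for d in days:
        if d.valid:
            counts[(d.week_index, d.is_weekend)] += 1
    return SubjectValidity(
        subject_id=next(iter(subject_ids)) if subject_ids else "",
        week1_valid_weekdays=counts[(1, False)],
        week1_valid_weekend_days=counts[(1, True)],
        week2_valid_weekdays=counts[(2, False)],
        week2_valid_weekend_days=counts[(2, True)],
    )


def split_days(epochs: EpochSeries) -> list[EpochSeries]:
    """Split a multi-day epoch series at civil midnights ([00:00, 24:00))."""
    ts = epochs.timestamps()
    days = pd.Series(ts.date)
    out = []
    for _, idx in days.groupby(days, sort=False).groups.items():
        i, j = idx[0], idx[-1] + 1
        out.append(epochs.slice(int(i), int(j)))
    return out
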