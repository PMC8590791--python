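"""Synthetic ground-truth generators.

Two families: (1) raw triaxial signals with planted activity segments of
known ENMO, planted low-variance non-wear blocks and planted sleep windows,
built so per-sample ENMO equals the target exactly (the sample vector is a
random unit direction scaled to norm 1 + target); (2) daily-summary tables
with subject random intercepts, day-of-week / season / reactivity effects
and covariates drawn from published cohort moments. All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as date_t, datetime, timedelta
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from wristpa.classify import season_of
from wristpa.errors import InputError, ScheduleError
from wristpa.raw import RawRecording

__all__ = [
    "Segment",
    "SegmentSchedule",
    "CovariateMoments",
    "GroupMoments",
    "GROUP_MOMENTS",
    "DailyEffectSpec",
    "gen_raw_recording",
    "gen_daily_dataset",
    "gen_vo2peak_cohort",
    "gen_subjects",
    "truth_epoch_flags",
]

SEGMENT_KINDS = ("activity", "nonwear", "sleep")
#: subject-id prefixes (group names share their first two letters)
_ID_PREFIX = {"HEART": "HF", "HEALTH": "HL"}
_SEASON_ORDER = ("Spring", "Summer", "Autumn", "Winter")
_CLASS_OUTCOMES = ("sedentary", "lpa", "mpa", "vpa", "bouted_mvpa", "sleep")


@dataclass(frozen=True)
class Segment:
    start_s: float
    duration_s: float
    kind: str  # activity | nonwear | sleep
    target_enmo: float = 0.0

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise ScheduleError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ScheduleError("segment duration must be positive")
        if self.target_enmo < 0:
            raise ScheduleError("target ENMO must be non-negative")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SegmentSchedule:
    """Non-overlapping segments over a recording span; uncovered gaps are
    quiet wear (target ENMO 0)."""

    segments: list
    total_duration_s: float

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: s.start_s)
        prev_end = 0.0
        for seg in self.segments:
            if seg.start_s < 0 or seg.end_s > self.total_duration_s + 1e-9:
                raise ScheduleError("segment extends beyond the recording span")
            if seg.start_s < prev_end - 1e-9:
                raise ScheduleError("segments overlap")
            prev_end = seg.end_s

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_duration_s": self.total_duration_s,
                "segments": [asdict(s) for s in self.segments],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SegmentSchedule":
        d = json.loads(text)
        return cls(
            segments=[Segment(**s) for s in d["segments"]],
            total_duration_s=d["total_duration_s"],
        )


def gen_raw_recording(
    schedule: SegmentSchedule,
    fs: float = 50.0,
    seed: int = 0,
    start_time: datetime = datetime(2019, 6, 3),
    device_id: str = "synthetic",
    nonwear_noise_sd: float = 0.003,
    nonwear_noise_clip: float = 0.0095,
) -> tuple[RawRecording, SegmentSchedule]:
    """Materialize a schedule into raw triaxial samples.

    Wear samples (activity, sleep and gap/quiet-wear) are random unit
    directions scaled to norm ``1 + target_enmo``, so per-sample ENMO
    equals the planted target exactly and per-axis variability stays far
    above non-wear thresholds. Non-wear samples are a fixed orientation
    plus clipped per-axis noise (SD < 0.005 g, range < 0.02 g). Returns the
    recording and a truth copy of the schedule.
    """
    if not (np.isfinite(fs) and fs > 0):
        raise InputError(f"sampling rate must be positive, got {fs!r}")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration_s * fs))
    target = np.zeros(n)
    nonwear = np.zeros(n, dtype=bool)
    for seg in schedule.segments:
        i0 = int(round(seg.start_s * fs))
        i1 = int(round(seg.end_s * fs))
        if seg.kind == "nonwear":
            nonwear[i0:i1] = True
        else:
            target[i0:i1] = seg.target_enmo
    xyz = np.empty((n, 3))
    wear_idx = ~nonwear
    n_wear = int(wear_idx.sum())
    if n_wear:
        dirs = rng.standard_normal((n_wear, 3))
        norms = np.linalg.norm(dirs, axis=1)
        norms[norms < 1e-12] = 1.0
        dirs /= norms[:, None]
        xyz[wear_idx] = dirs * (1.0 + target[wear_idx])[:, None]
    # one fixed orientation per contiguous non-wear block
    if nonwear.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], nonwear.view(np.int8), [0]])))
        for b0, b1 in zip(edges[::2], edges[1::2]):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            noise = np.clip(
                rng.normal(0.0, nonwear_noise_sd, (b1 - b0, 3)),
                -nonwear_noise_clip,
                nonwear_noise_clip,
            )
            xyz[b0:b1] = u + noise
    rec = RawRecording(
        start_time=start_time, fs=fs,
        x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
        device_id=device_id,
    )
    return rec, SegmentSchedule(list(schedule.segments), schedule.total_duration_s)


def truth_epoch_flags(
    schedule: SegmentSchedule, epoch_length: float, n_epochs: int
) -> pd.DataFrame:
    """Ground-truth per-epoch kind/target, from the segment covering each
    epoch midpoint (schedules aligned to epoch boundaries are exact)."""
    mids = (np.arange(n_epochs) + 0.5) * epoch_length
    kind = np.full(n_epochs, "wear", dtype=object)
    target = np.zeros(n_epochs)
    for seg in schedule.segments:
        m = (mids >= seg.start_s) & (mids < seg.end_s)
        kind[m] = seg.kind
        target[m] = seg.target_enmo
    return pd.DataFrame({"kind": kind, "target_enmo": target})


@dataclass(frozen=True)
class CovariateMoments:
    mean: float
    sd: float
    low: float
    high: float


@dataclass(frozen=True)
class GroupMoments:
    age: CovariateMoments
    vo2peak: CovariateMoments
    female_prop: float


#: published cohort moments (mean +/- SD, range) used as generator defaults
GROUP_MOMENTS = {
    "HEART": GroupMoments(
        age=CovariateMoments(66.0, 13.0, 26.0, 89.0),
        vo2peak=CovariateMoments(21.5, 6.4, 10.2, 39.5),
        female_prop=0.23,
    ),
    "HEALTH": GroupMoments(
        age=CovariateMoments(54.0, 19.0, 21.0, 91.0),
        vo2peak=CovariateMoments(34.4, 9.9, 14.2, 65.1),
        female_prop=0.51,
    ),
}


@lru_cache(maxsize=None)
def truncated_parent_params(
    mean: float, sd: float, low: float, high: float
) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [low, high]-truncation has the
    published mean and SD (asymmetric ranges bias naive rejection)."""
    def eqs(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = scipy.stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    mu, log_sigma = scipy.optimize.fsolve(eqs, [mean, np.log(sd)], full_output=False)
    return float(mu), float(np.exp(log_sigma))


def _truncnorm(rng, m: CovariateMoments, n: int) -> np.ndarray:
    """Rejection-sampled normal restricted to [low, high], parametrized so
    the truncated distribution matches the published mean/SD."""
    mu, sigma = truncated_parent_params(m.mean, m.sd, m.low, m.high)
    out = rng.normal(mu, sigma, n)
    bad = (out < m.low) | (out > m.high)
    while bad.any():
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = (out < m.low) | (out > m.high)
    return out


def gen_vo2peak_cohort(group: str, n: int, seed: int = 0) -> np.ndarray:
    """Peak-VO2 values (mL/kg/min) drawn from the group's published
    mean/SD, rejection-resampled into the published range."""
    if group not in GROUP_MOMENTS:
        raise InputError(f"unknown group {group!r}")
    if n < 1:
        raise InputError("n must be >= 1")
    return _truncnorm(np.random.default_rng(seed), GROUP_MOMENTS[group].vo2peak, n)


def gen_subjects(
    group: str, n: int, seed: int = 0, id_prefix: str | None = None
) -> pd.DataFrame:
    """Subject table (id, group, age, sex, vo2peak) with covariates drawn
    from the group's published moments."""
    if group not in GROUP_MOMENTS:
        raise InputError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    m = GROUP_MOMENTS[group]
    prefix = id_prefix if id_prefix is not None else _ID_PREFIX[group]
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i:04d}" for i in range(n)],
            "group": group,
            "age": _truncnorm(rng, m.age, n),
            "sex": np.where(rng.random(n) < m.female_prop, "female", "male"),
            "vo2peak": _truncnorm(rng, m.vo2peak, n),
        }
    )


@dataclass
class DailyEffectSpec:
    """Generative model for daily-summary tables.

    Minutes of class c for subject i on measurement day d:
    baseline + day-of-week effect + season effect + reactivity x (d-1)
    + subject intercept + residual, truncated to [0, wear minutes of the
    day]. Wear itself is generated first, truncated to [0, 1440].

    Effect fields accept a scalar / 7-vector / 4-vector applied to every
    outcome, or a dict mapping outcome name to one. Day-of-week effects
    are ordered Monday..Sunday; season effects Spring, Summer, Autumn,
    Winter.
    """

    n_subjects: dict = field(default_factory=lambda: {"HEART": 4, "HEALTH": 8})
    baseline_minutes: dict = field(
        default_factory=lambda: {
            "wear": 870.0, "sedentary": 620.0, "lpa": 180.0,
            "mpa": 55.0, "vpa": 10.0, "bouted_mvpa": 20.0, "sleep": 470.0,
        }
    )
    day_of_week_effects: object = 0.0
    season_effects: object = 0.0
    reactivity_slope: object = 0.0
    subject_sd: object = 8.0
    residual_sd: object = 15.0
    group_moments: dict = field(default_factory=lambda: dict(GROUP_MOMENTS))

    def _per_outcome(self, value, outcome: str, length: int | None) -> np.ndarray:
        if isinstance(value, dict):
            value = value.get(outcome, 0.0)
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if length is not None:
            if arr.size == 1:
                arr = np.full(length, arr[0])
            elif arr.size != length:
                raise InputError(
                    f"effect vector for {outcome!r} must have length {length}"
                )
        return arr

    def validate(self):
        for name in ("subject_sd", "residual_sd"):
            for outcome in self.baseline_minutes:
                v = self._per_outcome(getattr(self, name), outcome, None)
                if np.any(v < 0):
                    raise InputError(f"{name} must be non-negative")


def gen_daily_dataset(
    spec: DailyEffectSpec,
    n_days: int = 13,
    start_date: date_t = date_t(2019, 6, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Daily-summary table with known injected effects.

    One row per subject-day with calendar features, covariates and minutes
    per outcome; ``mvpa`` and ``tpa`` are derived sums, ``bouted_mvpa`` is
    clipped at ``mvpa``. Deterministic given (spec, seed).
    """
    if n_days < 1:
        raise InputError("n_days must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    outcomes = list(spec.baseline_minutes)
    if "wear" not in outcomes:
        raise InputError("baseline_minutes must include 'wear'")
    subj_frames = []
    for group, n in spec.n_subjects.items():
        if n:
            m = spec.group_moments[group]
            sf = pd.DataFrame(
                {
                    "subject_id": [f"{_ID_PREFIX[group]}{i:04d}" for i in range(n)],
                    "group": group,
                    "age": _truncnorm(rng, m.age, n),
                    "sex": np.where(rng.random(n) < m.female_prop, "female", "male"),
                    "vo2peak": _truncnorm(rng, m.vo2peak, n),
                }
            )
            subj_frames.append(sf)
    if not subj_frames:
        raise InputError("no subjects requested")
    subjects = pd.concat(subj_frames, ignore_index=True)
    n_subj = len(subjects)

    dates = [start_date + timedelta(days=d) for d in range(n_days)]
    dow_idx = np.array([d.weekday() for d in dates])
    season_idx = np.array([_SEASON_ORDER.index(season_of(d)) for d in dates])
    mdays = np.arange(1, n_days + 1)

    intercepts = {
        c: rng.normal(0.0, spec._per_outcome(spec.subject_sd, c, None)[0], n_subj)
        for c in outcomes
    }
    rows = {c: np.empty((n_subj, n_days)) for c in outcomes}
    for c in outcomes:
        dow_eff = spec._per_outcome(spec.day_of_week_effects, c, 7)
        sea_eff = spec._per_outcome(spec.season_effects, c, 4)
        slope = spec._per_outcome(spec.reactivity_slope, c, None)[0]
        res_sd = spec._per_outcome(spec.residual_sd, c, None)[0]
        mean = (
            spec.baseline_minutes[c]
            + dow_eff[dow_idx]
            + sea_eff[season_idx]
            + slope * (mdays - 1)
        )
        rows[c] = (
            mean[None, :]
            + intercepts[c][:, None]
            + rng.normal(0.0, res_sd, (n_subj, n_days))
        )
    wear = np.clip(rows["wear"], 0.0, 1440.0)
    for c in outcomes:
        if c != "wear":
            rows[c] = np.clip(rows[c], 0.0, wear)

    out = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects["subject_id"].values, n_days),
            "group": np.repeat(subjects["group"].values, n_days),
            "age": np.repeat(subjects["age"].values, n_days),
            "sex": np.repeat(subjects["sex"].values, n_days),
            "vo2peak": np.repeat(subjects["vo2peak"].values, n_days),
            "date": dates * n_subj,
            "measurement_day": np.tile(mdays, n_subj),
            "day_of_week": np.tile(
                np.array([d.strftime("%A") for d in dates], dtype=object), n_subj
            ),
            "is_weekend": np.tile(dow_idx >= 5, n_subj),
            "week_index": np.tile(np.where(mdays <= 7, 1, 2), n_subj),
            "season": np.tile(
                np.array([season_of(d) for d in dates], dtype=object), n_subj
            ),
            "wear_minutes": wear.ravel(),
        }
    )
    for c in outcomes:
        if c != "wear":
            out[f"{c}_minutes"] = rows[c].ravel()
    if {"mpa", "vpa"} <= set(outcomes):
        out["mvpa_minutes"] = out["mpa_minutes"] + out["vpa_minutes"]
        if "bouted_mvpa" in outcomes:
            out["bouted_mvpa_minutes"] = np.minimum(
                out["bouted_mvpa_minutes"], out["mvpa_minutes"]
            )
        if "lpa" in outcomes:
            out["tpa_minutes"] = out["mvpa_minutes"] + out["lpa_minutes"]
    out["valid"] = out["wear_minutes"] >= 600.0
    return out
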