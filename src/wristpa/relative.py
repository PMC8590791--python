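"""Relative-intensity audit of absolute MET-anchored cut-offs.

Maps fixed MET levels onto each subject's percent-of-peak-oxygen-uptake
scale and tabulates, per group and MET anchor, how the cohort distributes
over the relative intensity bands (LPA < 46%, MPA 46 to < 64%, VPA 64 to
100%, above capacity > 100%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from wristpa.errors import InputError

__all__ = [
    "RelativeBands",
    "Subject",
    "AuditResult",
    "met_to_pct",
    "band_of",
    "audit_cutoffs",
    "sweep_pct_curves",
    "ML_O2_PER_MET",
]

logger = logging.getLogger(__name__)

#: conventional oxygen cost of 1 MET, mL O2 per kg per min
ML_O2_PER_MET = 3.5

BANDS = ("LPA", "MPA", "VPA", "above_capacity")

#: the relative band each MET anchor is intended to land in
INTENDED_BAND = {2.0: "LPA", 3.0: "MPA", 4.5: "MPA", 6.0: "VPA", 8.0: "VPA"}


@dataclass(frozen=True)
class RelativeBands:
    """Relative-intensity band boundaries in percent of peak oxygen uptake."""

    lpa_upper: float = 46.0
    mpa_upper: float = 64.0
    capacity: float = 100.0

    def __post_init__(self):
        if not (0 < self.lpa_upper < self.mpa_upper <= self.capacity):
            raise InputError("band boundaries must satisfy 0 < lpa < mpa <= capacity")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str  # HEART | HEALTH
    age: float
    sex: str  # male | female
    vo2peak: float  # mL/kg/min

    def __post_init__(self):
        if self.vo2peak <= 0:
            raise InputError(f"vo2peak must be positive, got {self.vo2peak}")
        if self.age < 0:
            raise InputError(f"age must be non-negative, got {self.age}")


@dataclass
class AuditResult:
    """Band fractions per (group, MET anchor) cell.

    ``fractions``: rows (group, mets), columns LPA/MPA/VPA/above_capacity
    summing to 1 per row, plus n.
    ``placement``: per cell, fraction of subjects for whom the anchor lands
    below / within / above its intended band.
    """

    fractions: pd.DataFrame
    placement: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions.reset_index().to_dict(orient="records"),
            "placement": self.placement.reset_index().to_dict(orient="records"),
        }


def met_to_pct(
    mets: float, vo2peak: float, met_value: float = ML_O2_PER_MET
) -> float:
    """Oxygen cost of ``mets`` as a percentage of ``vo2peak``.

    Strictly decreasing in vo2peak and linear in mets.
    """
    if vo2peak <= 0 or mets <= 0 or met_value <= 0:
        raise InputError("mets, vo2peak and met_value must be positive")
    return 100.0 * (mets * met_value) / vo2peak


def band_of(pct: float, bands: RelativeBands = RelativeBands()) -> str:
    """Relative band of a %-of-peak value; exactly 100% is still VPA."""
    if pct < 0:
        raise InputError(f"negative percentage {pct}")
    if pct < bands.lpa_upper:
        return "LPA"
    if pct < bands.mpa_upper:
        return "MPA"
    if pct <= bands.capacity:
        return "VPA"
    return "above_capacity"


def _band_order(band: str) -> int:
    return BANDS.index(band)


def audit_cutoffs(
    subjects: Sequence[Subject],
    met_anchors: Iterable[float] = (2.0, 3.0, 6.0),
    bands: RelativeBands = RelativeBands(),
    met_value: float = ML_O2_PER_MET,
) -> AuditResult:
    """Classification-accuracy audit of absolute MET anchors.

    For each group and anchor: the fraction of subjects in each relative
    band, and the fraction for whom the anchor lands below / within /
    above its intended band (3 METs -> MPA, 6 METs -> VPA; above capacity
    counts as above).
    """
    if not subjects:
        raise InputError("no subjects to audit")
    frac_rows, place_rows = [], []
    groups = sorted({s.group for s in subjects})
    for group in groups:
        members = [s for s in subjects if s.group == group]
        if not members:
            logger.warning("group %s empty; skipped", group)
            continue
        for mets in met_anchors:
            assigned = [
                band_of(met_to_pct(mets, s.vo2peak, met_value), bands) for s in members
            ]
            n = len(assigned)
            frac = {b: assigned.count(b) / n for b in BANDS}
            frac_rows.append({"group": group, "mets": mets, **frac, "n": n})
            intended = INTENDED_BAND.get(float(mets))
            if intended is not None:
                tgt = _band_order(intended)
                orders = np.array([_band_order(b) for b in assigned])
                place_rows.append(
                    {
                        "group": group,
                        "mets": mets,
                        "intended_band": intended,
                        "below": float(np.mean(orders < tgt)),
                        "within": float(np.mean(orders == tgt)),
                        "above": float(np.mean(orders > tgt)),
                        "n": n,
                    }
                )
    fractions = pd.DataFrame(frac_rows).set_index(["group", "mets"])
    placement = (
        pd.DataFrame(place_rows).set_index(["group", "mets"])
        if place_rows
        else pd.DataFrame()
    )
    return AuditResult(fractions=fractions, placement=placement)


def sweep_pct_curves(
    subjects: Sequence[Subject],
    met_anchors: Iterable[float] = (2.0, 3.0, 6.0),
    axis: str = "age",
    met_value: float = ML_O2_PER_MET,
) -> pd.DataFrame:
    """Scatter points (axis value, percent of peak) per subject and anchor;
    pure reshaping of :func:`met_to_pct` for plotting."""
    if axis not in ("age", "vo2peak"):
        raise InputError(f"axis must be 'age' or 'vo2peak', got {axis!r}")
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "mets": mets,
            axis: getattr(s, axis),
            "pct_vo2peak": met_to_pct(mets, s.vo2peak, met_value),
        }
        for s in subjects
        for mets in met_anchors
    ]
    cols = ["subject_id", "group", "mets", axis, "pct_vo2peak"]
    return pd.DataFrame(rows, columns=cols)
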