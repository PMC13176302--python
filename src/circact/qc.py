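"""Wear-time quality control.

Two nested filters mirror the study's cleaning rules:

* day level — a calendar day is analyzable unless *more than* 6 h (360 min)
  of its 1-minute epochs are missing, counting both epochs flagged EXCLUDED
  (non-wear) and epochs absent from the recording (partial first/last days);
* participant level — a participant is retained only if a sleep diary exists
  and *not more than* 30% of the first 30 recorded days are invalid.

Boundary semantics are strict: exactly 360 missing minutes keeps a day,
exactly 30% invalid days keeps a participant.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MINUTES_PER_DAY, DiarySet, EpochSeries

logger = logging.getLogger(__name__)

MAX_MISSING_MINUTES = 360  # "more than 6 h" excludes a day
MAX_INVALID_FRACTION = 0.30  # "not more than 30%" of the first 30 days
GATE_WINDOW_DAYS = 30


@dataclass
class DayValidity:
    participant_id: str
    date: dt.date
    missing_minutes: int
    valid: bool


@dataclass
class CohortFlow:
    n_input: int
    n_excluded_no_diary: int
    n_excluded_weartime: int
    n_retained: int

    def __post_init__(self) -> None:
        assert self.n_retained == (
            self.n_input - self.n_excluded_no_diary - self.n_excluded_weartime
        )


@dataclass
class GateResult:
    retained: bool
    reason: str  # "ok" | "no_diary" | "weartime" | "short_record"

    def __bool__(self) -> bool:
        return self.retained


@dataclass
class ParticipantData:
    """A retained participant with their analyzable day set."""

    series: EpochSeries
    diary: DiarySet
    day_validity: list[DayValidity]
    valid_dates: list[dt.date] = field(init=False)

    def __post_init__(self) -> None:
        self.valid_dates = [d.date for d in self.day_validity if d.valid]


def day_validity(series: EpochSeries) -> list[DayValidity]:
    """Per-calendar-day missing-minute counts and validity for one series.

    Missing minutes are excluded epochs plus epochs not covered by the
    recording, so partial first/last days are usually invalid.
    """
    dates, _, valid = series.day_matrix()
    missing = MINUTES_PER_DAY - valid.sum(axis=1)
    return [
        DayValidity(
            participant_id=series.participant_id,
            date=date,
            missing_minutes=int(m),
            valid=bool(m <= MAX_MISSING_MINUTES),
        )
        for date, m in zip(dates, missing)
    ]


def participant_wear_gate(series: EpochSeries, diary: DiarySet | None) -> GateResult:
    """Retention gate: diary must exist and wear within the first 30 recorded
    days must be adequate (at most 30% invalid days)."""
    if diary is None or not diary.entries:
        return GateResult(False, "no_diary")
    if series.n < MINUTES_PER_DAY:
        return GateResult(False, "short_record")
    days = day_validity(series)[:GATE_WINDOW_DAYS]
    invalid_fraction = sum(not d.valid for d in days) / len(days)
    if invalid_fraction > MAX_INVALID_FRACTION:
        return GateResult(False, "weartime")
    return GateResult(True, "ok")


def apply_cohort_filters(
    cohort: dict[str, tuple[EpochSeries, DiarySet | None]],
) -> tuple[dict[str, ParticipantData], CohortFlow, pd.DataFrame]:
    """Apply both gates to a cohort.

    Returns the retained participants (each with invalid days removed from
    the analyzable day set), the cohort-flow accounting, and a QC report
    naming every excluded participant with its reason code.
    """
    retained: dict[str, ParticipantData] = {}
    report_rows = []
    n_no_diary = n_weartime = 0
    for pid in sorted(cohort):
        series, diary = cohort[pid]
        gate = participant_wear_gate(series, diary)
        if not gate:
            if gate.reason == "no_diary":
                n_no_diary += 1
            else:
                n_weartime += 1
            report_rows.append(
                {"participant_id": pid, "retained": False, "reason": gate.reason}
            )
            logger.info("excluded %s: %s", pid, gate.reason)
            continue
        validity = day_validity(series)
        retained[pid] = ParticipantData(series=series, diary=diary, day_validity=validity)
        report_rows.append({"participant_id": pid, "retained": True, "reason": "ok"})
    flow = CohortFlow(
        n_input=len(cohort),
        n_excluded_no_diary=n_no_diary,
        n_excluded_weartime=n_weartime,
        n_retained=len(retained),
    )
    if not retained:
        logger.warning("no participants retained")
    report = pd.DataFrame(report_rows, columns=["participant_id", "retained", "reason"])
    return retained, flow, report
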