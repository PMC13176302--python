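"""Relapse assignment, setting/phase labels and relapse-aligned week indexing.

Relapse is diary-defined: any day with self-reported alcohol during the
28-day outpatient follow-up puts the participant in the relapse group, and
the first such day is the relapse day.  Weeks count backward from the relapse
day (relapsers: week 1 is the 7 days before relapse, the relapse day opens
week 0 and the post-relapse phase) or from the end of recording
(non-relapsers: week 1 is the final 7 days).  Weekly statistics are only
computed for (week, setting) groups with at least 4 valid days.

Analyzable actigraphy is truncated at the first 30 recorded days, the same
horizon the wear-time gate inspects.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .errors import DataError
from .io import DiarySet, ParticipantManifest
from .qc import ParticipantData

FOLLOW_UP_DAYS = 28
MAX_RECORDED_DAYS = 30
MIN_DAYS_PER_WEEK = 4
HEAVY_DRINKING_THRESHOLD = {"female": 4, "male": 5, "not reported": 4}

WEEKLY_VARIABLES = ("IS", "IV")
DAILY_VARIABLES = ("M10", "L5", "RA", "wake_time", "wake_hours")


@dataclass
class RelapseAssignment:
    participant_id: str
    relapsed: bool
    relapse_date: dt.date | None
    days_until_relapse: int | None
    total_drinks: int
    heavy_drinking_days: int


def assign_relapse(
    diary: DiarySet,
    manifest: ParticipantManifest,
    follow_up_days: int = FOLLOW_UP_DAYS,
) -> RelapseAssignment:
    """Dichotomize one participant from the outpatient drinking diary.

    Outpatient day k is ``discharge_date + (k - 1)``; the window spans days
    1..follow_up_days.  Days without a diary entry count as missing, not as
    zero drinks.  Heavy drinking days use the 4 (female) / 5 (male) drink
    thresholds; the female threshold is applied when sex was not reported.
    """
    if not diary.entries:
        raise DataError(f"{manifest.participant_id}: no diary; participant should have been excluded upstream")
    threshold = HEAVY_DRINKING_THRESHOLD[manifest.sex]
    relapse_date = None
    total = heavy = 0
    for k in range(1, follow_up_days + 1):
        date = manifest.discharge_date + dt.timedelta(days=k - 1)
        drinks = diary.drinks_on(date)
        if drinks is None:
            continue
        total += drinks
        if drinks >= threshold:
            heavy += 1
        if drinks > 0 and relapse_date is None:
            relapse_date = date
    return RelapseAssignment(
        participant_id=manifest.participant_id,
        relapsed=relapse_date is not None,
        relapse_date=relapse_date,
        days_until_relapse=(
            (relapse_date - manifest.discharge_date).days + 1 if relapse_date else None
        ),
        total_drinks=total,
        heavy_drinking_days=heavy,
    )


def week_index(date: dt.date, anchor: dt.date) -> int:
    """Backward week index relative to ``anchor`` (the relapse day, or the day
    after the last recorded day).  Days before the anchor get indices 1, 2, ...
    counting backward in 7-day blocks; the anchor day opens week 0."""
    delta = (date - anchor).days
    if delta < 0:
        return 1 + (-delta - 1) // 7
    return -(delta // 7)


def label_days(
    participant: ParticipantData,
    assignment: RelapseAssignment,
    manifest: ParticipantManifest,
) -> pd.DataFrame:
    """One row per analyzable day: date, setting, phase, week index.

    Every valid day maps to exactly one (week, setting, phase) triple; the
    relapse day belongs to week 0 and the post-relapse phase.
    """
    start = participant.series.start.date()
    horizon = start + dt.timedelta(days=MAX_RECORDED_DAYS)
    dates = [d for d in participant.valid_dates if d < horizon]
    if not dates:
        return pd.DataFrame(columns=["date", "setting", "phase", "week"])
    if assignment.relapsed:
        if assignment.relapse_date < start:
            raise DataError(
                f"{assignment.participant_id}: relapse precedes actigraphy start"
            )
        anchor = assignment.relapse_date
    else:
        anchor = max(dates) + dt.timedelta(days=1)
    rows = []
    for date in dates:
        outpatient = date >= manifest.discharge_date
        post = assignment.relapsed and date >= assignment.relapse_date
        rows.append(
            {
                "date": date,
                "setting": "outpatient" if outpatient else "inpatient",
                "phase": ("post" if post else "pre") if assignment.relapsed else "none",
                "week": week_index(date, anchor),
            }
        )
    return pd.DataFrame(rows)


def weekly_groups(labels: pd.DataFrame) -> list[tuple[int, str, list[dt.date]]]:
    """(week, setting, dates) groups eligible for weekly statistics (>= 4 valid days)."""
    out = []
    for (week, setting), grp in labels.groupby(["week", "setting"]):
        if len(grp) >= MIN_DAYS_PER_WEEK:
            out.append((int(week), setting, sorted(grp["date"])))
    return sorted(out, key=lambda t: (-t[0], t[1]))


def discharge_groups(
    labels: pd.DataFrame, manifest: ParticipantManifest
) -> list[tuple[str, str, list[dt.date]]] | None:
    """The pre/post-discharge weekly groups, or None when the participant does
    not qualify for the discharge analysis (fewer than 4 valid inpatient days).

    Returns up to two groups: all valid inpatient days (the one valid
    inpatient week) and the valid pre-relapse days of the first outpatient
    week.  Post-relapse days are excluded so the discharge contrast is not
    contaminated by the separate relapse effect of early relapsers.
    """
    inpt = sorted(labels.loc[labels["setting"] == "inpatient", "date"])
    if len(inpt) < MIN_DAYS_PER_WEEK:
        return None
    first_week_end = manifest.discharge_date + dt.timedelta(days=6)
    eligible = labels[(labels["setting"] == "outpatient") & (labels["phase"] != "post")]
    out1 = sorted(d for d in eligible["date"] if d <= first_week_end)
    groups = [("inpatient_week", "inpatient", inpt)]
    if len(out1) >= MIN_DAYS_PER_WEEK:
        groups.append(("first_outpatient_week", "outpatient", out1))
    return groups


def inpatient_subset(
    labeled: dict[str, pd.DataFrame],
) -> list[str]:
    """Participants with at least 4 valid inpatient days (the discharge-analysis set)."""
    return [
        pid
        for pid, labels in sorted(labeled.items())
        if (labels["setting"] == "inpatient").sum() >= MIN_DAYS_PER_WEEK
    ]


def build_observation_rows(
    daily: pd.DataFrame,
    weekly: pd.DataFrame,
    assignments: dict[str, RelapseAssignment],
    variable: str,
    family: str,
) -> pd.DataFrame:
    """Model-ready long-format rows for one variable and one model family.

    ``daily``/``weekly`` are the tidy metric tables produced by the pipeline
    (see :mod:`circact.pipeline`).  Families:

    * ``discharge`` — the pre/post-discharge contrast on the inpatient
      subset: weekly variables use the dedicated discharge grouping, daily
      variables the inpatient days plus the first outpatient week;
    * ``relapse_probability`` — pre-relapse rows only, with the participant's
      binary relapse outcome attached;
    * ``relapse_effect`` — all rows with the post-relapse indicator.

    Weekly variables (IS, IV) contribute one row per (week, setting) group,
    daily variables one row per valid day.
    """
    if variable in WEEKLY_VARIABLES:
        base, unit_col = weekly, "unit"
    elif variable in DAILY_VARIABLES:
        base, unit_col = daily, "date"
    else:
        raise ValueError(f"unknown variable {variable!r}")

    frame = base.copy()
    if variable == "wake_hours":
        frame["value"] = frame["wake_time"] / 3600.0
    else:
        frame["value"] = frame[variable]

    if family == "discharge":
        if variable in WEEKLY_VARIABLES:
            frame = frame[frame["scheme"] == "discharge"]
        else:
            # pre-relapse only: early relapses must not contaminate the contrast
            frame = frame[frame["in_discharge_window"] & (frame["phase"] != "post")]
    elif family in ("relapse_probability", "relapse_effect"):
        if variable in WEEKLY_VARIABLES:
            frame = frame[frame["scheme"] == "relapse"]
        if family == "relapse_probability":
            frame = frame[frame["phase"] != "post"]
    else:
        raise ValueError(f"unknown model family {family!r}")

    out = pd.DataFrame(
        {
            "participant": frame["participant"].to_numpy(),
            "unit": frame[unit_col].to_numpy(),
            "outpatient": (frame["setting"] == "outpatient").astype(int).to_numpy(),
            "post_relapse": (frame["phase"] == "post").astype(int).to_numpy(),
            "value": frame["value"].to_numpy(),
        }
    )
    if family == "relapse_probability":
        out["relapsed"] = [
            int(assignments[p].relapsed) for p in out["participant"]
        ]
    return out.dropna(subset=["value"]).reset_index(drop=True)
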