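import datetime as dt

import numpy as np
import pandas as pd
import pytest

from circact.errors import DataError
from circact.io import DiaryEntry, DiarySet, EpochSeries, ParticipantManifest
from circact.qc import ParticipantData, day_validity
from circact.windows import (
    assign_relapse,
    build_observation_rows,
    discharge_groups,
    inpatient_subset,
    label_days,
    week_index,
    weekly_groups,
)

START = dt.date(2024, 1, 1)


def manifest(discharge_day=4, sex="female", pid="P1"):
    return ParticipantManifest(
        participant_id=pid,
        discharge_date=START + dt.timedelta(days=discharge_day),
        sex=sex,
    )


def diary(drinks_by_day, pid="P1", n_days=35):
    """drinks_by_day maps study-day offsets (0-based from START) to drinks."""
    ds = DiarySet(pid)
    for k in range(n_days):
        ds.add(
            DiaryEntry(
                START + dt.timedelta(days=k), None, None, int(drinks_by_day.get(k, 0))
            )
        )
    return ds


def participant(n_days=32, pid="P1"):
    series = EpochSeries(
        pid,
        dt.datetime.combine(START, dt.time()),
        np.ones(n_days * 1440),
        np.zeros(n_days * 1440, bool),
    )
    return ParticipantData(series=series, diary=diary({}, pid, n_days), day_validity=day_validity(series))


class TestAssignRelapse:
    def test_all_zero_diary(self):
        a = assign_relapse(diary({}), manifest())
        assert not a.relapsed
        assert a.relapse_date is None and a.days_until_relapse is None
        assert a.total_drinks == 0 and a.heavy_drinking_days == 0

    def test_female_four_drinks_day_eleven(self):
        # discharge on day 4; outpatient day 11 = study-day offset 14
        a = assign_relapse(diary({14: 4}), manifest(sex="female"))
        assert a.relapsed
        assert a.days_until_relapse == 11
        assert a.heavy_drinking_days == 1

    def test_male_threshold_is_five(self):
        drinks = {k: 4 for k in range(4, 32)}
        a = assign_relapse(diary(drinks), manifest(sex="male"))
        assert a.relapsed and a.days_until_relapse == 1
        assert a.heavy_drinking_days == 0
        assert a.total_drinks == 4 * 28

    def test_drinks_before_discharge_ignored(self):
        a = assign_relapse(diary({2: 6}), manifest())
        assert not a.relapsed

    def test_missing_diary_days_are_missing_not_zero(self):
        ds = diary({10: 3}, n_days=12)  # diary ends before the full follow-up
        a = assign_relapse(ds, manifest())
        assert a.relapsed and a.days_until_relapse == 7

    def test_empty_diary_errors(self):
        with pytest.raises(DataError):
            assign_relapse(DiarySet("P1"), manifest())


class TestWeekIndexing:
    def test_relapser_backward_weeks(self):
        # relapse on study day 15 (1-based): days 8..14 are week 1, day 15 opens week 0
        anchor = START + dt.timedelta(days=14)
        for offset, expected in [(7, 1), (13, 1), (14, 0), (20, 0), (21, -1), (6, 2)]:
            assert week_index(START + dt.timedelta(days=offset), anchor) == expected

    def test_nonrelapser_final_week_is_week_one(self):
        last = START + dt.timedelta(days=27)
        anchor = last + dt.timedelta(days=1)
        assert week_index(last, anchor) == 1
        assert week_index(last - dt.timedelta(days=6), anchor) == 1
        assert week_index(last - dt.timedelta(days=7), anchor) == 2

    def test_partition_every_day_exactly_one_triple(self):
        part = participant()
        a = assign_relapse(diary({18: 5}, n_days=32), manifest())
        labels = label_days(part, a, manifest())
        assert labels["date"].is_unique
        assert len(labels) == 30  # truncated at 30 recorded days
        assert set(labels.columns) == {"date", "setting", "phase", "week"}

    def test_relapse_day_in_week_zero_and_post(self):
        part = participant()
        a = assign_relapse(diary({18: 5}, n_days=32), manifest())
        labels = label_days(part, a, manifest()).set_index("date")
        rd = a.relapse_date
        assert labels.loc[rd, "week"] == 0
        assert labels.loc[rd, "phase"] == "post"
        assert labels.loc[rd - dt.timedelta(days=1), "phase"] == "pre"

    def test_week_with_three_valid_days_has_no_weekly_group(self):
        part = participant(n_days=32)
        a = assign_relapse(diary({}, n_days=32), manifest())
        labels = label_days(part, a, manifest())
        # drop all but 3 days of one interior week
        week2 = labels[labels["week"] == 2]["date"].tolist()
        keep = ~labels["date"].isin(week2[3:])
        groups = weekly_groups(labels[keep])
        assert all(len(dates) >= 4 for _, _, dates in groups)
        assert 2 not in [w for w, s, _ in groups if s == "outpatient"] or len(week2) <= 3

    def test_relapse_before_actigraphy_errors(self):
        part = participant()
        bad = assign_relapse(diary({18: 5}, n_days=32), manifest())
        bad.relapse_date = START - dt.timedelta(days=1)
        with pytest.raises(DataError):
            label_days(part, bad, manifest())


class TestDischargeSubset:
    @pytest.mark.parametrize("n_inpatient,included", [(5, True), (4, True), (2, False)])
    def test_minimum_inpatient_days(self, n_inpatient, included):
        part = participant()
        a = assign_relapse(diary({}, n_days=32), manifest(discharge_day=n_inpatient))
        labels = label_days(part, a, manifest(discharge_day=n_inpatient))
        subset = inpatient_subset({"P1": labels})
        assert ("P1" in subset) is included
        groups = discharge_groups(labels, manifest(discharge_day=n_inpatient))
        assert (groups is not None) is included
        if included:
            units = [u for u, _, _ in groups]
            assert units == ["inpatient_week", "first_outpatient_week"]
            inpt = dict((u, d) for u, _, d in groups)["inpatient_week"]
            assert len(inpt) == n_inpatient

    def test_subset_matches_bruteforce_recount(self, small_cohort):
        from circact.pipeline import analyze_cohort

        res = analyze_cohort(
            small_cohort.series, small_cohort.diaries, small_cohort.manifest,
            detect_wake=False,
        )
        truth = small_cohort.truth.set_index("participant_id")
        for pid in res.daily["participant"].unique():
            valid_inpt = len(
                res.daily[(res.daily.participant == pid) & (res.daily.setting == "inpatient")]
            )
            assert (pid in res.inpatient_subset) == (valid_inpt >= 4)
            # programmed inpatient span bounds the valid inpatient day count
            assert valid_inpt <= truth.loc[pid, "n_inpatient_days"]


class TestObservationRows:
    def setup_method(self):
        self.daily = pd.DataFrame(
            {
                "participant": ["A"] * 4 + ["B"] * 4,
                "date": [START + dt.timedelta(days=k) for k in range(4)] * 2,
                "setting": ["inpatient", "outpatient", "outpatient", "outpatient"] * 2,
                "phase": ["pre", "pre", "post", "post", "none", "none", "none", "none"],
                "week": [2, 1, 0, 0] * 2,
                "M10": [300.0, 310, 320, 330, 290, 280, 300, 310],
                "L5": [10.0] * 8,
                "RA": [290.0, 300, 310, 320, 280, 270, 290, 300],
                "wake_time": [25200.0] * 8,
                "in_discharge_window": [True] * 4 + [False] * 4,
            }
        )
        self.weekly = pd.DataFrame(
            {
                "participant": ["A", "A", "B"],
                "scheme": ["relapse", "discharge", "relapse"],
                "unit": ["w1:outpatient", "inpatient_week", "w1:outpatient"],
                "week": [1, np.nan, 1],
                "setting": ["outpatient", "inpatient", "outpatient"],
                "phase": ["pre", "none", "none"],
                "IS": [0.2, 0.25, 0.22],
                "IV": [0.4, 0.6, 0.42],
                "n_days": [7, 5, 7],
            }
        )
        self.assignments = {
            "A": type("A_", (), {"relapsed": True})(),
            "B": type("A_", (), {"relapsed": False})(),
        }

    def test_relapse_probability_rows_exclude_post(self):
        rows = build_observation_rows(
            self.daily, self.weekly, self.assignments, "M10", "relapse_probability"
        )
        assert (rows[rows.participant == "A"]["post_relapse"] == 0).all()
        assert len(rows[rows.participant == "A"]) == 2  # pre-relapse rows only
        assert len(rows[rows.participant == "B"]) == 4
        assert set(rows["relapsed"][rows.participant == "A"]) == {1}

    def test_relapse_effect_rows_flag_post(self):
        rows = build_observation_rows(
            self.daily, self.weekly, self.assignments, "M10", "relapse_effect"
        )
        a = rows[rows.participant == "A"]
        assert list(a["post_relapse"]) == [0, 0, 1, 1]
        assert (rows[rows.participant == "B"]["post_relapse"] == 0).all()

    def test_discharge_rows_use_window_and_scheme(self):
        daily_rows = build_observation_rows(
            self.daily, self.weekly, self.assignments, "M10", "discharge"
        )
        assert set(daily_rows["participant"]) == {"A"}
        weekly_rows = build_observation_rows(
            self.daily, self.weekly, self.assignments, "IV", "discharge"
        )
        assert list(weekly_rows["unit"]) == ["inpatient_week"]

    def test_wake_hours_conversion(self):
        rows = build_observation_rows(
            self.daily, self.weekly, self.assignments, "wake_hours", "relapse_probability"
        )
        assert rows["value"].iloc[0] == pytest.approx(7.0)

    def test_unknown_variable_and_family(self):
        with pytest.raises(ValueError):
            build_observation_rows(self.daily, self.weekly, self.assignments, "foo", "discharge")
        with pytest.raises(ValueError):
            build_observation_rows(self.daily, self.weekly, self.assignments, "IV", "bar")
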