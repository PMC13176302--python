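import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circact.metrics import (
    HourlySeries,
    daily_m10_l5_ra,
    daily_metrics_matrix,
    hourly_summaries,
    interdaily_stability,
    intradaily_variability,
)

DATES7 = np.array([dt.date(2024, 1, 1) + dt.timedelta(days=d) for d in range(7)])


def full_valid(counts):
    return np.ones_like(counts, dtype=bool)


def week_from_hour_values(hour_values):
    """7 identical days whose 24 hourly values are constant within each hour."""
    day = np.repeat(np.asarray(hour_values, dtype=float), 60)
    counts = np.tile(day, (7, 1))
    return hourly_summaries(DATES7, counts, full_valid(counts))


# ---------------------------------------------------------------------------
# independent naive oracles (plain double loops over the stated formulas)


def naive_is(week_counts):
    epochs = week_counts.ravel()
    xbar = epochs.mean()
    hod = np.zeros(24)
    for h in range(24):
        vals = []
        for d in range(week_counts.shape[0]):
            vals.extend(week_counts[d, h * 60 : (h + 1) * 60])
        hod[h] = np.mean(vals)
    num = sum((m - xbar) ** 2 for m in hod) / 23
    den = sum((x - xbar) ** 2 for x in epochs) / (epochs.size - 1)
    return num / den


def naive_iv(week_counts):
    means = []
    for d in range(week_counts.shape[0]):
        for h in range(24):
            means.append(week_counts[d, h * 60 : (h + 1) * 60].mean())
    n_h = len(means)
    m = np.mean(means)
    num = sum((means[j] - means[j - 1]) ** 2 for j in range(1, n_h)) / (n_h - 1)
    den = sum((x - m) ** 2 for x in means) / (n_h - 1)
    return num / den


class TestHourlySummaries:
    def test_constant_signal(self):
        h = week_from_hour_values([10.0] * 24)
        assert h.overall_mean == 10.0
        np.testing.assert_allclose(h.hour_of_day_means, 10.0)
        assert h.n_epochs == 10080

    def test_two_hour_day(self):
        day = np.concatenate([np.zeros(60), np.full(60, 60.0)])
        counts = day.reshape(1, -1)
        # pad to a full day: remaining hours absent (invalid)
        counts = np.concatenate([counts, np.zeros((1, 1440 - 120))], axis=1)
        valid = np.zeros_like(counts, dtype=bool)
        valid[0, :120] = True
        h = hourly_summaries(DATES7[:1], counts, valid)
        np.testing.assert_array_equal(h.hourly_means[:2], [0.0, 60.0])
        assert np.isnan(h.hourly_means[2:]).all()

    def test_sub_thirty_minute_hours_absent(self):
        counts = np.ones((1, 1440))
        valid = np.ones_like(counts, dtype=bool)
        valid[0, 0:31] = False  # hour 0 has 29 valid minutes
        h = hourly_summaries(DATES7[:1], counts, valid)
        assert np.isnan(h.hourly_means[0])
        assert h.hourly_means[1] == 1.0

    def test_calendar_gaps_become_absent_hours(self):
        counts = np.ones((2, 1440))
        dates = np.array([dt.date(2024, 1, 1), dt.date(2024, 1, 3)])  # day 2 missing
        h = hourly_summaries(dates, counts, full_valid(counts))
        assert h.hourly_means.size == 72
        assert np.isnan(h.hourly_means[24:48]).all()

    def test_zero_valid_epochs_error(self):
        counts = np.ones((1, 1440))
        with pytest.raises(ValueError):
            hourly_summaries(DATES7[:1], counts, np.zeros_like(counts, bool))

    def test_random_series_against_bruteforce(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(7, 1440)).astype(float)
        h = hourly_summaries(DATES7, counts, full_valid(counts))
        for hr in range(24):
            expected = np.mean([counts[d, hr * 60 : (hr + 1) * 60] for d in range(7)])
            assert h.hour_of_day_means[hr] == pytest.approx(expected, rel=1e-12)


class TestInterdailyStability:
    def test_constant_signal_undefined(self):
        assert np.isnan(interdaily_stability(week_from_hour_values([5.0] * 24)))

    def test_periodic_closed_form(self):
        """Hour-constant daily-periodic week: IS = (N-1)p/((p-1)N) exactly."""
        h = week_from_hour_values(np.arange(24, dtype=float))
        expected = (10080 - 1) * 24 / (23 * 10080)
        assert interdaily_stability(h) == pytest.approx(expected, abs=1e-12)

    def test_iid_noise_expectation(self):
        """For white-noise epochs IS is ~ 1/420 (hour-of-day means average 420 epochs)."""
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(40):
            counts = rng.normal(50, 10, size=(7, 1440))
            h = hourly_summaries(DATES7, counts, full_valid(counts))
            vals.append(interdaily_stability(h))
        assert np.mean(vals) == pytest.approx(1 / 420, rel=0.15)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(6, size=(7, 1440)).astype(float)
        h1 = hourly_summaries(DATES7, counts, full_valid(counts))
        h2 = hourly_summaries(DATES7, counts * 7.5, full_valid(counts))
        assert interdaily_stability(h1) == pytest.approx(interdaily_stability(h2), rel=1e-10)
        assert intradaily_variability(h1) == pytest.approx(
            intradaily_variability(h2), rel=1e-10
        )


class TestIntradailyVariability:
    def test_constant_hourly_means_zero(self):
        day = np.repeat(np.arange(60.0), 24).reshape(24, 60).T.ravel()  # varies in-hour
        counts = np.tile(np.repeat([5.0] * 24, 60), (7, 1))
        counts += np.tile(np.arange(1440) % 2, (7, 1))  # minute noise, constant hourly mean
        h = hourly_summaries(DATES7, counts, full_valid(counts))
        assert intradaily_variability(h) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_square_wave(self):
        """168 hourly means alternating 0/100: IV = 10000 / (420000/167)."""
        h = week_from_hour_values([0.0, 100.0] * 12)
        expected = 10000 / (420000 / 167)
        assert intradaily_variability(h) == pytest.approx(expected, rel=1e-12)

    def test_white_noise_hourly_means_near_two(self):
        rng = np.random.default_rng(23)
        vals = []
        for _ in range(200):
            means = rng.normal(size=168)
            h = HourlySeries((), means, np.full(24, np.nan), 0.0, 1.0, 10080)
            vals.append(intradaily_variability(h))
        assert np.mean(vals) == pytest.approx(2.0, rel=0.02)

    def test_gap_pairs_skipped(self):
        means = np.array([1.0, 2.0, np.nan, 10.0, 11.0])
        h = HourlySeries((), means, np.full(24, np.nan), 0.0, 1.0, 100)
        n_h = 4
        m = np.nanmean(means)
        num = ((2 - 1) ** 2 + (11 - 10) ** 2) / (n_h - 1)
        den = np.nansum((means - m) ** 2) / (n_h - 1)
        assert intradaily_variability(h) == pytest.approx(num / den, rel=1e-12)


class TestDailyM10L5:
    def test_block_profile(self):
        day = np.zeros(1440)
        day[8 * 60 : 18 * 60] = 100.0 / 60  # hourly totals 100 for 10 hours
        m10, l5, ra = daily_m10_l5_ra(day, np.ones(1440, bool))
        assert (m10, l5, ra) == (pytest.approx(100.0), pytest.approx(0.0), pytest.approx(100.0))

    def test_linear_hourly_totals(self):
        day = np.repeat(np.arange(1, 25, dtype=float) / 60, 60)  # T_h = h+1
        m10, l5, ra = daily_m10_l5_ra(day, np.ones(1440, bool))
        assert m10 == pytest.approx(np.mean(np.arange(15, 25)))  # 19.5
        assert l5 == pytest.approx(3.0)
        assert ra == pytest.approx(16.5)

    def test_partial_hour_rescaled(self):
        day = np.ones(1440)
        valid = np.ones(1440, bool)
        valid[0:30] = False  # hour 0 has 30 valid minutes -> total rescaled to 60
        m10, l5, ra = daily_m10_l5_ra(day, valid)
        assert l5 == pytest.approx(60.0)
        assert m10 == pytest.approx(60.0)

    def test_too_few_computable_hours_skipped(self):
        day = np.ones(1440)
        valid = np.zeros(1440, bool)
        valid[: 10 * 60] = True  # only 10 computable hours
        assert np.isnan(daily_m10_l5_ra(day, valid)[0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**32 - 1))
    def test_sort_oracle_property(self, seed):
        """M10/L5 equal an independent sort-based ranking of hourly totals."""
        rng = np.random.default_rng(seed)
        day = rng.poisson(rng.uniform(0.5, 8), size=1440).astype(float)
        m10, l5, ra = daily_m10_l5_ra(day, np.ones(1440, bool))
        totals = sorted(day[h * 60 : (h + 1) * 60].sum() for h in range(24))
        assert m10 == pytest.approx(np.mean(totals[-10:]), rel=1e-12)
        assert l5 == pytest.approx(np.mean(totals[:5]), rel=1e-12)
        assert ra == pytest.approx(m10 - l5, rel=1e-12)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(4, size=(5, 1440)).astype(float)
        valid = rng.random((5, 1440)) > 0.05
        mat = daily_metrics_matrix(counts, valid)
        for d in range(5):
            expected = daily_m10_l5_ra(counts[d], valid[d])
            np.testing.assert_allclose(mat[d], expected, rtol=1e-12)


def test_is_iv_match_naive_oracles_on_random_weeks():
    """Vectorized IS/IV equal plain double-loop evaluations of the formulas."""
    rng = np.random.default_rng(99)
    for _ in range(20):
        base = rng.uniform(0.5, 6)
        counts = rng.poisson(base, size=(7, 1440)).astype(float)
        counts[:, 420:1320] += rng.poisson(5, size=(7, 900))  # diurnal structure
        h = hourly_summaries(DATES7, counts, full_valid(counts))
        assert interdaily_stability(h) == pytest.approx(naive_is(counts), abs=1e-10)
        assert intradaily_variability(h) == pytest.approx(naive_iv(counts), abs=1e-10)
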