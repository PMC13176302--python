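"""Nonparametric circadian rest-activity statistics.

Interdaily stability (IS) and intradaily variability (IV) are the classic
variance-ratio measures of rest-activity rhythm regularity and fragmentation,
computed here on weekly groups of 1-minute epochs:

    IS = [ sum_h (Xbar_h - Xbar)^2 / (p - 1) ] / [ sum_i (X_i - Xbar)^2 / (N - 1) ]
    IV = [ sum_j (Xbar_j - Xbar_{j-1})^2 / (N_h - 1) ] / [ sum_j (Xbar_j - m)^2 / (N_h - 1) ]

with X_i the valid 1-minute epochs of the group, Xbar_h the p = 24
hour-of-day means pooled over the group's days, Xbar_j the chronological
per-calendar-hour means, m their mean and N_h their number.  Both statistics
use *sample* variances (the N-1 / p-1 terms), not the population variances of
the original formulation, so complete periodic data yields an IS slightly
above 1 (by the factor (N-1)p / ((p-1)N)).

M10 / L5 are daily summaries: hourly activity totals are ranked and the ten
largest (M10) and five smallest (L5) averaged; the relative amplitude RA is
their plain difference M10 - L5.

Undefined statistics (zero-variance denominators, too little valid data)
propagate as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MINUTES_PER_DAY

P_HOURS = 24
#: an hourly mean is only computed from at least this many valid minutes
MIN_VALID_MINUTES_PER_HOUR = 30
#: a day needs at least this many computable hourly totals for M10/L5
MIN_COMPUTABLE_HOURS = 15


@dataclass
class HourlySeries:
    """Hourly summaries of one (participant, week, setting) group of valid days."""

    key: tuple
    hourly_means: np.ndarray  # chronological per-calendar-hour means; NaN = absent hour
    hour_of_day_means: np.ndarray  # 24 pooled hour-of-day means; NaN = unpopulated
    overall_mean: float
    epoch_ss: float  # sum of squared deviations of valid epochs about overall_mean
    n_epochs: int

    @property
    def n_hours(self) -> int:
        return int(np.sum(np.isfinite(self.hourly_means)))


def hourly_summaries(dates, counts, valid, key: tuple = ()) -> HourlySeries:
    """Summarize one group's valid days into hourly means.

    ``counts``/``valid`` are ``(D, 1440)`` rows for the group's valid days
    (chronological, one row per day in ``dates``).  Calendar gaps between the
    supplied days are expanded to absent hours so that lag-1 hourly pairs
    never span a skipped day.  Hours with fewer than 30 valid minutes are
    absent; hour-of-day means pool every valid epoch sharing the wall-clock
    hour label across all days.
    """
    dates = np.asarray(dates)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    if counts.shape != valid.shape or counts.shape[1] != MINUTES_PER_DAY:
        raise ValueError("counts and valid must be (D, 1440) and congruent")
    if not valid.any():
        raise ValueError("group has zero valid epochs")

    # expand onto the contiguous date range so gaps appear as absent hours
    offsets = np.array([(d - dates[0]).days for d in dates])
    span = int(offsets[-1]) + 1
    full_counts = np.full((span, MINUTES_PER_DAY), np.nan)
    full_valid = np.zeros((span, MINUTES_PER_DAY), dtype=bool)
    full_counts[offsets] = counts
    full_valid[offsets] = valid

    c = np.where(full_valid, full_counts, 0.0).reshape(span, P_HOURS, 60)
    v = full_valid.reshape(span, P_HOURS, 60)
    hour_sums = c.sum(axis=2)
    hour_minutes = v.sum(axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        hourly_means = np.where(
            hour_minutes >= MIN_VALID_MINUTES_PER_HOUR, hour_sums / hour_minutes, np.nan
        ).ravel()
        pooled_minutes = hour_minutes.sum(axis=0)
        hod_means = np.where(pooled_minutes > 0, hour_sums.sum(axis=0) / pooled_minutes, np.nan)

    epochs = full_counts[full_valid]
    overall = float(epochs.mean())
    return HourlySeries(
        key=key,
        hourly_means=hourly_means,
        hour_of_day_means=hod_means,
        overall_mean=overall,
        epoch_ss=float(np.sum((epochs - overall) ** 2)),
        n_epochs=epochs.size,
    )


def interdaily_stability(h: HourlySeries) -> float:
    """IS of one weekly group; NaN when undefined (constant signal, <2 epochs)."""
    populated = np.isfinite(h.hour_of_day_means)
    if h.n_epochs < 2 or populated.sum() < 2:
        return float("nan")
    denominator = h.epoch_ss / (h.n_epochs - 1)
    if denominator == 0.0:
        return float("nan")
    numerator = (
        np.sum((h.hour_of_day_means[populated] - h.overall_mean) ** 2) / (P_HOURS - 1)
    )
    return float(numerator / denominator)


def intradaily_variability(h: HourlySeries) -> float:
    """IV of one weekly group; lag-1 pairs spanning an absent hour are skipped."""
    x = h.hourly_means
    finite = np.isfinite(x)
    n_h = int(finite.sum())
    if n_h < 3:
        return float("nan")
    m = float(np.nanmean(x))
    denominator = float(np.nansum((x - m) ** 2)) / (n_h - 1)
    pair = finite[1:] & finite[:-1]
    diffs = x[1:][pair] - x[:-1][pair]
    numerator = float(np.sum(diffs**2)) / (n_h - 1)
    if denominator == 0.0:
        # constant hourly means: no hour-to-hour fragmentation at all
        return 0.0 if numerator == 0.0 else float("nan")
    return float(numerator / denominator)


def hourly_totals(counts_day: np.ndarray, valid_day: np.ndarray) -> np.ndarray:
    """24 hourly activity totals of one day; partial hours rescaled to a 60-min
    equivalent, hours under 30 valid minutes NaN (not computable)."""
    c = np.where(valid_day, counts_day, 0.0).reshape(P_HOURS, 60)
    v = valid_day.reshape(P_HOURS, 60).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = np.where(v >= MIN_VALID_MINUTES_PER_HOUR, c.sum(axis=1) * 60.0 / v, np.nan)
    return totals


def daily_m10_l5_ra(counts_day: np.ndarray, valid_day: np.ndarray):
    """(M10, L5, RA) for one day; all NaN when fewer than 15 hours are computable."""
    totals = hourly_totals(np.asarray(counts_day, float), np.asarray(valid_day, bool))
    t = totals[np.isfinite(totals)]
    if t.size < MIN_COMPUTABLE_HOURS:
        return float("nan"), float("nan"), float("nan")
    t.sort()
    m10 = float(t[-10:].mean())
    l5 = float(t[:5].mean())
    return m10, l5, m10 - l5


def daily_metrics_matrix(counts: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Vectorized (D, 3) array of per-day (M10, L5, RA) for a day matrix."""
    counts = np.atleast_2d(counts)
    valid = np.atleast_2d(valid)
    d = counts.shape[0]
    c = np.where(valid, counts, 0.0).reshape(d, P_HOURS, 60)
    v = valid.reshape(d, P_HOURS, 60).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = np.where(v >= MIN_VALID_MINUTES_PER_HOUR, c.sum(axis=2) * 60.0 / v, np.nan)
    out = np.full((d, 3), np.nan)
    computable = np.isfinite(totals)
    enough = computable.sum(axis=1) >= MIN_COMPUTABLE_HOURS
    # rank with NaN pushed to the top, then read off sorted positions
    ranked = np.sort(np.where(computable, totals, np.inf), axis=1)
    n_comp = computable.sum(axis=1)
    for i in np.flatnonzero(enough):
        t = ranked[i, : n_comp[i]]
        out[i, 0] = t[-10:].mean()
        out[i, 1] = t[:5].mean()
        out[i, 2] = out[i, 0] - out[i, 1]
    return out
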