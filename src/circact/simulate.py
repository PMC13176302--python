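"""Synthetic actigraphy cohorts with programmed discharge and relapse effects.

The generator emulates the data streams of an inpatient-to-outpatient
actigraphy study: per participant, 1-minute activity counts from a two-state
(rest/active) diurnal process, a sleep/alcohol diary, and a manifest entry.
The rest-active profile has

* a participant-level habitual wake time plus day-to-day jitter (the jitter
  SD controls realized interdaily stability),
* within-day fragmentation injected as state-flip bouts (sedentary spells
  suppressing activity inside the active span) whose daily rate controls
  realized intradaily variability,
* overdispersed (negative binomial) counts while active and sparse Poisson
  counts while at rest,
* random non-wear runs marked EXCLUDED,
* programmed condition effects: discharge shifts the wake time and activity
  levels and changes the fragmentation rate; an optional relapse day shifts
  the wake time again and changes fragmentation once more.

Fragmentation has two layers: state-flip sedentary bouts at a fixed daily
rate (the fragmentation dial), and mean-preserving lognormal modulation of
the hourly activity level.  Because weekly IV is a nonlinear functional of
these processes, programmed IV levels are hit by calibration: the generator
estimates the modulation-SD to expected-weekly-IV map by Monte Carlo under
a fixed internal seed, makes it monotone, and inverts it per condition.
Programmed IV deltas are therefore exact differences of calibrated
expectations, recorded in the truth table.

All randomness flows through one seeded generator; per-participant
substreams are spawned deterministically, so identical spec + seed yields a
byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import SpecError
from .io import (
    MINUTES_PER_DAY,
    DiaryEntry,
    DiarySet,
    EpochSeries,
    ParticipantManifest,
)
from .metrics import hourly_summaries, intradaily_variability

SECONDS_PER_DAY = 86400
_CALIBRATION_SEED = 20_240_917  # fixed: the bout-rate -> IV map is part of the design
CONDITIONS = ("inpatient", "outpatient_pre", "outpatient_post")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_participants: int = 103
    seed: int = 0
    start_date: dt.date = dt.date(2024, 1, 1)
    #: P(inpatient wear = 0..7 days); median 2 days, ~35% with >= 4 days
    inpatient_day_weights: tuple = (0.10, 0.22, 0.18, 0.15, 0.12, 0.09, 0.07, 0.07)
    outpatient_days: int = 28
    relapse_fraction: float = 26 / 103
    relapse_day_mean: float = 10.5
    relapse_day_sd: float = 6.09
    # activity profile
    rest_mean: float = 0.2  # counts/min asleep
    active_mean: float = 5.0  # counts/min awake (hourly totals ~ 300)
    active_dispersion: float = 4.0  # negative binomial size
    active_between_sd: float = 0.20  # lognormal sigma of participant active level
    wake_base_s: float = 21600.0  # 06:00 (structured clinic schedule)
    wake_between_sd_s: float = 2700.0
    wake_jitter_sd_s: float = 1800.0
    sleep_duration_s: float = 32400.0  # 9 h; bedtime follows the same day's condition
    # programmed condition effects
    discharge_wake_delta_s: float = 3461.0
    relapse_wake_delta_s: float = 3190.0
    baseline_iv: float = 0.43  # expected weekly IV, outpatient pre-relapse
    discharge_iv_delta: float = -0.214  # outpatient minus inpatient
    relapse_iv_delta: float = -0.08  # post- minus pre-relapse
    discharge_active_mult: float = 1.12
    discharge_rest_mult: float = 0.75
    # within-day fragmentation: sedentary state-flip bouts at a fixed daily
    # rate, plus per-condition hourly activity modulation calibrated to the
    # programmed IV levels
    bout_rate_per_day: float = 0.75
    bout_mean_minutes: float = 45.0
    bout_max_minutes: float = 120.0
    # missingness and diary fidelity
    nonwear_runs_per_day: float = 0.05
    nonwear_mean_minutes: float = 90.0
    diary_noise_s: float = 900.0

    def __post_init__(self) -> None:
        if not 0 <= self.relapse_fraction <= 1:
            raise SpecError("relapse_fraction outside [0, 1]")
        if self.relapse_day_mean > self.outpatient_days:
            raise SpecError("relapse day beyond the outpatient follow-up")
        if abs(sum(self.inpatient_day_weights) - 1) > 1e-9:
            raise SpecError("inpatient_day_weights must sum to 1")

    def condition_iv_targets(self) -> dict[str, float]:
        return {
            "inpatient": self.baseline_iv - self.discharge_iv_delta,
            "outpatient_pre": self.baseline_iv,
            "outpatient_post": self.baseline_iv + self.relapse_iv_delta,
        }

    def condition_profile(self, condition: str) -> tuple:
        """(active_mean, rest_mean, wake_delta_s) of a condition."""
        if condition == "inpatient":
            return self.active_mean, self.rest_mean, 0.0
        wake = self.discharge_wake_delta_s
        if condition == "outpatient_post":
            wake += self.relapse_wake_delta_s
        return (
            self.active_mean * self.discharge_active_mult,
            self.rest_mean * self.discharge_rest_mult,
            wake,
        )


@dataclass
class Cohort:
    spec: CohortSpec
    series: dict[str, EpochSeries]
    diaries: dict[str, DiarySet]
    manifest: dict[str, ParticipantManifest]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# low-level day simulation (shared by cohort generation and IV calibration)


def _draw_counts(rng: np.random.Generator, active: np.ndarray, mean_active, r: float, k: float):
    """Negative binomial counts while active, Poisson while at rest.

    ``mean_active`` may be a scalar or a per-minute array (hourly modulation)."""
    counts = np.empty(active.size, dtype=np.float64)
    n_act = int(active.sum())
    m = mean_active[active] if np.ndim(mean_active) else mean_active
    counts[active] = rng.negative_binomial(k, k / (k + m), size=n_act)
    counts[~active] = rng.poisson(r, size=active.size - n_act)
    return counts


def _hour_factors(z: np.ndarray, sigma: float) -> np.ndarray:
    """Mean-preserving lognormal hour-level activity factors from standard
    normal draws ``z`` (one per clock hour)."""
    return np.exp(sigma * z - sigma**2 / 2)


def _day_schedule(
    rng: np.random.Generator, spec: CohortSpec, conditions: list[str], wake_base_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (wake, bed) seconds from each day's own condition.

    Wake and bed carry the condition's wake-shift plus independent day-to-day
    jitter; the active span is ``86400 - sleep_duration`` long on average.
    Bed may pass midnight (spill into the next calendar day) under extreme
    jitter; at the default operating point this is rare for every condition.
    """
    n_days = len(conditions)
    deltas = np.array([spec.condition_profile(c)[2] for c in conditions])
    wake = wake_base_s + deltas + rng.normal(0, spec.wake_jitter_sd_s, n_days)
    wake = np.clip(wake, 2 * 3600, 14 * 3600)
    active_span = SECONDS_PER_DAY - spec.sleep_duration_s
    bed = wake_base_s + deltas + active_span + rng.normal(0, spec.wake_jitter_sd_s, n_days)
    bed = np.maximum(bed, wake + 4 * 3600)
    return wake, bed


def _active_profile(wake_s: np.ndarray, bed_s: np.ndarray) -> np.ndarray:
    """Minute-level active mask given per-day wake and bed seconds (bed may
    exceed 86400, spilling activity into the next calendar day)."""
    n_days = len(wake_s)
    active = np.zeros(n_days * MINUTES_PER_DAY, dtype=bool)
    for d in range(n_days):
        start = d * MINUTES_PER_DAY + int(round(wake_s[d] / 60.0))
        stop = d * MINUTES_PER_DAY + int(round(bed_s[d] / 60.0))
        active[max(start, 0) : min(stop, active.size)] = True
    return active


def _inject_bouts(
    rng: np.random.Generator,
    active: np.ndarray,
    rate_per_day: float,
    mean_minutes: float,
    max_minutes: float,
):
    """Fragment the active span with Poisson-arriving sedentary bouts.

    Bout starts arrive uniformly; each suppresses activity for an
    exponential length truncated at ``max_minutes``.  Bouts only turn active
    minutes into rest (sedentary spells, not nocturnal awakenings), so the
    day's principal rest period — and with it the programmed wake time —
    stays intact at any fragmentation rate.
    """
    if rate_per_day <= 0:
        return active
    n_days = active.size // MINUTES_PER_DAY
    n_bouts = rng.poisson(rate_per_day * n_days)
    if n_bouts == 0:
        return active
    starts = rng.integers(0, active.size, size=n_bouts)
    lengths = np.round(
        np.clip(rng.exponential(mean_minutes, size=n_bouts), 5, max_minutes)
    ).astype(int)
    mask = np.zeros(active.size, dtype=bool)
    for s, l in zip(starts, lengths):
        mask[s : s + l] = True
    return active & ~mask


def _simulate_condition_days(
    rng: np.random.Generator,
    spec: CohortSpec,
    condition: str,
    n_days: int,
    modulation_sd: float,
    wake_base_s: float,
    active_level: float,
    bout_rate: float | None = None,
) -> np.ndarray:
    """Counts for ``n_days`` of one participant held in one condition."""
    a, r, _ = spec.condition_profile(condition)
    wake, bed = _day_schedule(rng, spec, [condition] * n_days, wake_base_s)
    active = _active_profile(wake, bed)
    rate = spec.bout_rate_per_day if bout_rate is None else bout_rate
    active = _inject_bouts(rng, active, rate, spec.bout_mean_minutes, spec.bout_max_minutes)
    factors = _hour_factors(rng.normal(size=n_days * 24), modulation_sd)
    mean_active = a * active_level * np.repeat(factors, 60)
    return _draw_counts(rng, active, mean_active, r, spec.active_dispersion)


# ---------------------------------------------------------------------------
# fragmentation calibration


def _expected_weekly_iv(
    spec: CohortSpec,
    condition: str,
    modulation_sd: float,
    n_weeks: int,
    seed: int,
) -> float:
    """Population-mean weekly IV under one condition at one hourly-modulation SD.

    Each replicate scores the interior 7 days of a 9-day simulation (one
    burn-in and one trailing day), so late bedtimes spilling past midnight
    contribute the same transitions they do inside a cohort recording; the
    inpatient condition is instead scored on standalone leading blocks of
    4-7 days, the shape of its one valid week.

    Variance-reduction design: the participant profile (wake base, activity
    level, jitter, sedentary bouts) and the standard-normal field behind the
    hourly modulation depend only on ``seed``, not on ``modulation_sd``, so
    evaluations across the calibration grid and across conditions share
    their noise and Monte-Carlo error largely cancels in the inversion.
    """
    profile_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    mod_rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    counts_rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    a, r, _ = spec.condition_profile(condition)
    k = spec.active_dispersion
    block_days = _inpatient_block_days(spec) if condition == "inpatient" else None
    ivs = []
    for i in range(n_weeks):
        level = float(
            np.exp(profile_rng.normal(-spec.active_between_sd**2 / 2, spec.active_between_sd))
        )
        base = float(profile_rng.normal(spec.wake_base_s, spec.wake_between_sd_s))
        wake, bed = _day_schedule(profile_rng, spec, [condition] * 9, base)
        active = _active_profile(wake, bed)
        active = _inject_bouts(
            profile_rng, active, spec.bout_rate_per_day,
            spec.bout_mean_minutes, spec.bout_max_minutes,
        )
        factors = _hour_factors(mod_rng.normal(size=9 * 24), modulation_sd)
        mean_active = a * level * np.repeat(factors, 60)
        counts = _draw_counts(counts_rng, active, mean_active, r, k)
        days = counts.reshape(9, MINUTES_PER_DAY)
        if block_days is None:
            # interior 7-day week of a longer recording
            scored = days[1:8]
        else:
            # standalone leading block, the shape of the one valid inpatient week
            scored = days[: block_days[i % len(block_days)]]
        dates = np.array(
            [spec.start_date + dt.timedelta(days=d) for d in range(len(scored))]
        )
        h = hourly_summaries(dates, scored, np.ones_like(scored, dtype=bool))
        ivs.append(intradaily_variability(h))
    return float(np.mean(ivs))


def _inpatient_block_days(spec: CohortSpec) -> list[int]:
    """Deterministic cycle over inpatient block lengths >= 4 days, with
    multiplicities approximating their conditional probabilities."""
    weights = spec.inpatient_day_weights[4:]
    total = sum(weights)
    if total <= 0:
        return [7]
    out: list[int] = []
    for d, w in zip(range(4, 8), weights):
        out.extend([d] * max(int(round(10 * w / total)), 0))
    return out or [7]


_CALIBRATION_GRID = (0.0, 0.05, 0.1, 0.15, 0.22, 0.3, 0.42, 0.6, 0.85)
_CALIBRATION_WEEKS = 160
_REFINE_WEEKS = 480


@lru_cache(maxsize=8)
def _calibrate_spec(spec_key: tuple) -> dict[str, tuple[float, float]]:
    from scipy.interpolate import PchipInterpolator
    from scipy.optimize import brentq

    spec = CohortSpec(**dict(spec_key))
    out = {}
    for condition in CONDITIONS:
        target = spec.condition_iv_targets()[condition]
        grid_iv = np.array(
            [
                _expected_weekly_iv(
                    spec, condition, sd, n_weeks=_CALIBRATION_WEEKS, seed=_CALIBRATION_SEED
                )
                for sd in _CALIBRATION_GRID
            ]
        )
        grid_iv = np.maximum.accumulate(grid_iv)  # enforce monotone map
        if not grid_iv[0] <= target <= grid_iv[-1]:
            raise SpecError(
                f"target IV {target:.3f} for {condition} outside the feasible "
                f"range [{grid_iv[0]:.3f}, {grid_iv[-1]:.3f}] of the modulation process"
            )
        # strictly increasing support for smooth monotone inversion
        keep = np.concatenate(([True], np.diff(grid_iv) > 0))
        curve = PchipInterpolator(np.array(_CALIBRATION_GRID)[keep], grid_iv[keep])
        lo, hi = _CALIBRATION_GRID[0], _CALIBRATION_GRID[-1]
        if target <= curve(lo):
            sd = float(lo)
        else:
            sd = float(brentq(lambda s: float(curve(s)) - target, lo, hi))
        # one Newton polish with a larger replicate budget at the operating
        # point: removes the residual Monte-Carlo offset of the curve
        if sd > lo:
            refined = _expected_weekly_iv(
                spec, condition, sd, n_weeks=_REFINE_WEEKS, seed=_CALIBRATION_SEED + 1
            )
            slope = max(float(curve.derivative()(sd)), 1e-3)
            sd = float(np.clip(sd - (refined - target) / slope, lo, hi))
        out[condition] = (sd, target)
    return out


def calibrated_modulation(spec: CohortSpec) -> dict[str, tuple[float, float]]:
    """Per-condition (hourly modulation SD, expected weekly IV) hitting the
    spec's programmed IV levels."""
    key = tuple(
        (f.name, getattr(spec, f.name))
        for f in dataclasses.fields(spec)
        if f.name not in ("n_participants", "seed")
    )
    return _calibrate_spec(key)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort (epoch series, diaries, manifest, truth record)."""
    rates = calibrated_modulation(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_participants + 1)
    head_rng = np.random.default_rng(seeds[0])

    n_inpatient = head_rng.choice(
        len(spec.inpatient_day_weights), size=spec.n_participants, p=spec.inpatient_day_weights
    )
    relapsed = head_rng.random(spec.n_participants) < spec.relapse_fraction
    relapse_day = np.clip(
        np.round(head_rng.normal(spec.relapse_day_mean, spec.relapse_day_sd, spec.n_participants)),
        1,
        spec.outpatient_days,
    ).astype(int)

    series: dict[str, EpochSeries] = {}
    diaries: dict[str, DiarySet] = {}
    manifest: dict[str, ParticipantManifest] = {}
    truth_rows = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(seeds[i + 1])
        row = _generate_participant(
            rng, spec, pid, int(n_inpatient[i]), bool(relapsed[i]), int(relapse_day[i]), rates
        )
        series[pid], diaries[pid], manifest[pid] = row[:3]
        truth_rows.append(row[3])
    truth = pd.DataFrame(truth_rows)
    return Cohort(spec=spec, series=series, diaries=diaries, manifest=manifest, truth=truth)


def _generate_participant(rng, spec, pid, n_in, relapsed, relapse_day, rates):
    n_days = n_in + spec.outpatient_days
    discharge = spec.start_date + dt.timedelta(days=n_in)
    relapse_date = (
        discharge + dt.timedelta(days=relapse_day - 1) if relapsed else None
    )
    wake_base = float(rng.normal(spec.wake_base_s, spec.wake_between_sd_s))
    level = float(np.exp(rng.normal(-spec.active_between_sd**2 / 2, spec.active_between_sd)))

    conditions = []
    for d in range(n_days):
        if d < n_in:
            conditions.append("inpatient")
        elif relapsed and d - n_in >= relapse_day - 1:
            conditions.append("outpatient_post")
        else:
            conditions.append("outpatient_pre")

    wake_s, bed_s = _day_schedule(rng, spec, conditions, wake_base)
    active = _active_profile(wake_s, bed_s)
    # fragment and draw counts per contiguous condition block
    counts = np.empty(n_days * MINUTES_PER_DAY)
    for cond in CONDITIONS:
        day_idx = [d for d in range(n_days) if conditions[d] == cond]
        if not day_idx:
            continue
        sl = slice(day_idx[0] * MINUTES_PER_DAY, (day_idx[-1] + 1) * MINUTES_PER_DAY)
        block = _inject_bouts(
            rng, active[sl], spec.bout_rate_per_day,
            spec.bout_mean_minutes, spec.bout_max_minutes,
        )
        a, r, _ = spec.condition_profile(cond)
        factors = _hour_factors(rng.normal(size=len(day_idx) * 24), rates[cond][0])
        mean_active = a * level * np.repeat(factors, 60)
        counts[sl] = _draw_counts(rng, block, mean_active, r, spec.active_dispersion)

    excluded = _draw_nonwear(rng, n_days, spec)
    epoch = EpochSeries(
        participant_id=pid,
        start=dt.datetime.combine(spec.start_date, dt.time()),
        counts=counts,
        excluded=excluded,
    )

    diary = _generate_diary(rng, spec, pid, n_days, wake_s, bed_s, n_in, relapse_day if relapsed else None)
    sex = "female" if rng.random() < 0.32 else "male"
    mani = ParticipantManifest(
        participant_id=pid,
        discharge_date=discharge,
        sex=sex,
        covariates={"age": round(float(np.clip(rng.normal(48.6, 11.3), 21, 75)), 1)},
    )
    truth = {
        "participant_id": pid,
        "n_inpatient_days": n_in,
        "relapsed": relapsed,
        "relapse_day": relapse_day if relapsed else np.nan,
        "relapse_date": relapse_date,
        "discharge_date": discharge,
        "wake_base_s": wake_base,
        "active_level": level,
        "wake_delta_discharge_s": spec.discharge_wake_delta_s,
        "wake_delta_relapse_s": spec.relapse_wake_delta_s,
        "iv_inpatient": rates["inpatient"][1],
        "iv_outpatient_pre": rates["outpatient_pre"][1],
        "iv_outpatient_post": rates["outpatient_post"][1],
    }
    return epoch, diary, mani, truth


def _draw_nonwear(rng, n_days, spec) -> np.ndarray:
    excluded = np.zeros(n_days * MINUTES_PER_DAY, dtype=bool)
    n_runs = rng.poisson(spec.nonwear_runs_per_day * n_days)
    if n_runs:
        starts = rng.integers(0, excluded.size, size=n_runs)
        lengths = np.maximum(
            10, np.round(rng.exponential(spec.nonwear_mean_minutes, size=n_runs))
        ).astype(int)
        for s, l in zip(starts, lengths):
            excluded[s : s + l] = True
    return excluded


def _generate_diary(rng, spec, pid, n_days, wake_s, bed_s, n_in, relapse_day):
    diary = DiarySet(participant_id=pid)
    for d in range(n_days):
        date = spec.start_date + dt.timedelta(days=d)
        wake = wake_s[d] + rng.normal(0, spec.diary_noise_s)
        bed = bed_s[d] + rng.normal(0, spec.diary_noise_s)
        drinks = 0
        out_day = d - n_in + 1  # 1-based outpatient day index
        if relapse_day is not None and out_day >= relapse_day:
            if out_day == relapse_day:
                drinks = 1 + int(rng.poisson(3))
            elif rng.random() < 0.5:
                drinks = 1 + int(rng.poisson(3))
        diary.add(
            DiaryEntry(
                date=date,
                bed_time=_seconds_to_time(bed % SECONDS_PER_DAY),
                wake_time=_seconds_to_time(wake % SECONDS_PER_DAY),
                drinks=drinks,
            )
        )
    return diary


def _seconds_to_time(s: float) -> dt.time:
    m = int(s) // 60
    return dt.time(m // 60 % 24, m % 60)


# ---------------------------------------------------------------------------
# missingness injection and the cohort-flow fixture


def inject_missingness(
    series: EpochSeries,
    rng: np.random.Generator,
    runs_per_day: float = 0.05,
    mean_minutes: float = 90.0,
    force_gate_failure: bool = False,
) -> EpochSeries:
    """Return a copy of ``series`` with additional EXCLUDED non-wear runs.

    With ``force_gate_failure`` the injection deterministically invalidates
    more than 30% of the first 30 recorded days (7-h runs on 11 distinct
    days), so the participant fails the wear-time gate.
    """
    excluded = series.excluded.copy()
    if force_gate_failure:
        n_days = min(series.n // MINUTES_PER_DAY, 30)
        days = rng.choice(n_days, size=min(11, n_days), replace=False)
        for d in days:
            start = d * MINUTES_PER_DAY + int(rng.integers(0, MINUTES_PER_DAY - 7 * 60))
            excluded[start : start + 7 * 60] = True
    else:
        n_runs = rng.poisson(runs_per_day * max(series.n // MINUTES_PER_DAY, 1))
        if n_runs:
            starts = rng.integers(0, series.n, size=n_runs)
            lengths = np.maximum(10, np.round(rng.exponential(mean_minutes, size=n_runs))).astype(int)
            for s, l in zip(starts, lengths):
                excluded[s : s + l] = True
    return EpochSeries(
        participant_id=series.participant_id,
        start=series.start,
        counts=series.counts.copy(),
        excluded=excluded,
    )


def figure1_preset(seed: int = 0) -> Cohort:
    """126-participant fixture: 5 diaryless, 18 gate-failing, 103 retained."""
    spec = CohortSpec(n_participants=126, seed=seed)
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1)).generate_state(1)[0])
    pids = sorted(cohort.series)
    diaryless = pids[:5]
    gate_failing = pids[5:23]
    for pid in diaryless:
        cohort.diaries[pid] = DiarySet(participant_id=pid)
        cohort.manifest[pid].has_diary = False
    for pid in gate_failing:
        cohort.series[pid] = inject_missingness(
            cohort.series[pid], rng, force_gate_failure=True
        )
    cohort.truth["designed_exclusion"] = [
        "no_diary" if p in diaryless else "weartime" if p in gate_failing else ""
        for p in cohort.truth["participant_id"]
    ]
    return cohort
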