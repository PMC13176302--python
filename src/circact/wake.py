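"""Daily wake-time (activity-onset) detection.

Each valid day's wake time is the first rest-to-active transition after the
day's principal rest period, found by a three-stage rule in the spirit of
automatic rest/activity on-off detectors for actimetry:

1. smooth the 1-minute counts with a centered median (rank) filter at two
   widths: a coarse scale that erases fragmentation bouts shorter than about
   half its width, and a fine scale that preserves the morning edge;
2. binarize each against an adaptive threshold taken from quantiles of the
   smoothed distribution inside a 24-h detection window (18:00 of the
   previous day to 18:00 of the target day), which makes the estimate
   invariant to rescaling the counts;
3. morphologically clean short active bursts, locate the principal rest
   period as the longest coarse rest run of at least ``min_rest_run`` minutes
   ending during the target day, then refine the wake edge to the nearest
   fine-scale rest-to-active transition.

Days without a detectable rest period (flat signal, insufficient contrast)
yield an absent estimate with low confidence.  Detection is deterministic
for fixed parameters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .io import MINUTES_PER_DAY, EpochSeries
from .qc import day_validity

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class WakeParams:
    """Detection settings; defaults validated on synthetic two-state days."""

    filter_width: int = 121  # minutes, fine-scale centered rank/median filter
    coarse_width: int = 241  # minutes, coarse filter locating the rest period
    low_quantile: float = 0.10
    high_quantile: float = 0.90
    threshold_fraction: float = 0.25  # threshold at q_lo + fraction * (q_hi - q_lo)
    min_rel_contrast: float = 0.30  # (q_hi - q_lo)/q_hi below this => no rest period
    low_conf_contrast: float = 0.60  # below this => estimate kept but flagged low
    min_active_run: int = 60  # minutes; shorter active bursts folded into rest
    min_rest_run: int = 120  # minutes; minimum principal rest duration
    refine_window: int = 120  # minutes; fine edge searched within this of the coarse edge
    window_start_hour: int = -6  # detection window start, hours from midnight
    latest_wake_hour: int = 18  # principal rest must end before this hour


DEFAULT_WAKE_PARAMS = WakeParams()


@dataclass
class WakeEstimate:
    participant_id: str
    date: dt.date
    wake_time: float | None  # seconds from the day's midnight
    confidence: str  # "ok" | "low"


def _runs(mask: np.ndarray):
    """(start, stop, value) runs of a boolean array; stop is exclusive."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [mask.size]))
    return list(zip(starts, stops, mask[starts]))


def _smooth(series: EpochSeries, params: WakeParams) -> tuple[np.ndarray, np.ndarray]:
    filled = pd.Series(np.where(series.excluded, np.nan, series.counts))
    filled = filled.ffill().bfill().to_numpy()
    fine = median_filter(filled, size=params.filter_width, mode="nearest")
    coarse = median_filter(filled, size=params.coarse_width, mode="nearest")
    return fine, coarse


def detect_wake_times(
    series: EpochSeries,
    params: WakeParams = DEFAULT_WAKE_PARAMS,
    valid_dates=None,
) -> list[WakeEstimate]:
    """One wake estimate per valid calendar day of ``series``.

    ``valid_dates`` restricts detection to the given days; by default all
    days passing the day-level wear filter are used.
    """
    if valid_dates is None:
        valid_dates = [d.date for d in day_validity(series) if d.valid]
    fine, coarse = _smooth(series, params)
    first_midnight = dt.datetime.combine(series.start.date(), dt.time())
    lead = int((series.start - first_midnight).total_seconds()) // 60

    out = []
    for date in valid_dates:
        day_offset = (date - first_midnight.date()).days
        midnight_idx = day_offset * MINUTES_PER_DAY - lead
        lo = midnight_idx + params.window_start_hour * 60
        hi = midnight_idx + params.latest_wake_hour * 60
        sl = slice(max(lo, 0), min(hi, series.n))
        wake_time, confidence = _detect_one(
            fine[sl], coarse[sl], max(lo, 0) - midnight_idx, params
        )
        out.append(
            WakeEstimate(
                participant_id=series.participant_id,
                date=date,
                wake_time=wake_time,
                confidence=confidence,
            )
        )
    return out


def _binarize(window: np.ndarray, threshold: float, min_active_run: int) -> np.ndarray:
    active = window >= threshold
    # fold sub-minimum active bursts into rest
    for start, stop, value in _runs(active):
        if value and stop - start < min_active_run:
            active[start:stop] = False
    return active


def _detect_one(
    fine_win: np.ndarray, coarse_win: np.ndarray, window_offset_min: int, params: WakeParams
):
    """Detect the wake edge inside one detection window.

    ``window_offset_min`` is the minute-of-day (possibly negative) of the
    window's first sample relative to the target day's midnight.
    """
    if fine_win.size < params.min_rest_run:
        return None, "low"
    q_lo, q_hi = np.quantile(fine_win, [params.low_quantile, params.high_quantile])
    if q_hi <= 0:
        return None, "low"
    contrast = (q_hi - q_lo) / q_hi
    if contrast < params.min_rel_contrast:
        return None, "low"
    threshold = q_lo + params.threshold_fraction * (q_hi - q_lo)

    # principal rest period on the coarse scale
    coarse_active = _binarize(coarse_win, threshold, params.min_active_run)
    best = None
    for start, stop, value in _runs(coarse_active):
        if value or stop - start < params.min_rest_run:
            continue
        end_minute = stop + window_offset_min  # first active minute after the run
        if 0 <= end_minute < params.latest_wake_hour * 60 and stop < coarse_win.size:
            if best is None or (stop - start) > (best[1] - best[0]):
                best = (start, stop)
    if best is None:
        return None, "low"
    coarse_edge = best[1]

    # refine to the nearest fine-scale rest-to-active transition
    fine_active = _binarize(fine_win, threshold, params.min_active_run)
    edge = coarse_edge
    best_dist = params.refine_window + 1
    for start, stop, value in _runs(fine_active):
        if value or stop >= fine_win.size:
            continue
        dist = abs(stop - coarse_edge)
        if dist <= params.refine_window and dist < best_dist:
            best_dist, edge = dist, stop
    wake_minute = edge + window_offset_min
    if not 0 <= wake_minute < params.latest_wake_hour * 60:
        return None, "low"
    confidence = "ok" if contrast >= params.low_conf_contrast else "low"
    return float(wake_minute * 60), confidence


def wake_seconds_to_clock(wake_time: float) -> str:
    """Render seconds-from-midnight as zero-padded 24-h ``HH:MM`` (seconds truncated)."""
    if not 0 <= wake_time < SECONDS_PER_DAY:
        raise ValueError(f"wake_time {wake_time} outside [0, 86400)")
    minutes = int(wake_time) // 60
    return f"{minutes // 60:02d}:{minutes % 60:02d}"
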