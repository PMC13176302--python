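"""Reading and writing actigraphy epoch exports, sleep/alcohol diaries and the manifest.

The on-disk formats are Actiware-style delimited text: one row per 1-minute
epoch carrying a wall-clock timestamp, an activity count and a non-wear
(EXCLUDED) flag.  The exact column names, delimiter and header offset vary
between software versions, so they are configurable through
:class:`EpochDialect`; the default dialect is the one the synthetic cohort
writer emits.

Timestamps are naive local wall-clock throughout: a daylight-saving
transition simply shows up as a 23- or 25-hour calendar day, and all
hour-of-day labels downstream are taken from wall-clock time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

EPOCH_SECONDS = 60
MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class EpochDialect:
    """Column layout of an Actiware-style epoch export."""

    delimiter: str = ","
    date_col: str = "Date"
    time_col: str = "Time"
    activity_col: str = "Activity"
    excluded_col: str = "Excluded"
    skip_rows: int = 0
    date_format: str = "%Y-%m-%d"
    time_format: str = "%H:%M:%S"


DEFAULT_DIALECT = EpochDialect()


@dataclass
class EpochSeries:
    """One participant's chronological 1-minute activity counts.

    ``counts[k]`` is the activity count of the epoch starting at
    ``start + k * 60 s``; ``excluded[k]`` is True when that epoch was flagged
    as non-wear.  The grid is dense: there are no gaps, and absent wear is
    expressed through the excluded flag, never by dropping rows.
    """

    participant_id: str
    start: dt.datetime
    counts: np.ndarray
    excluded: np.ndarray
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.counts.ndim != 1 or self.excluded.ndim != 1:
            raise DataError("counts and excluded must be 1-D")
        if len(self.counts) != len(self.excluded):
            raise DataError(
                f"counts (n={len(self.counts)}) and excluded (n={len(self.excluded)}) differ in length"
            )
        if len(self.counts) == 0:
            raise DataError("empty epoch series")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise DataError("activity counts must be finite and non-negative")
        if self.epoch_seconds != EPOCH_SECONDS:
            raise DataError("only 60-s epochs are supported")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        return len(self.counts)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n, freq="60s")

    def day_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Reshape the series onto whole calendar days.

        Returns ``(dates, counts, valid)`` where ``dates`` holds one
        :class:`datetime.date` per overlapped calendar day, ``counts`` is a
        ``(D, 1440)`` float array (NaN where the recording does not cover the
        epoch) and ``valid`` a boolean ``(D, 1440)`` mask that is True only
        for recorded, non-excluded epochs.  Midnight-to-midnight, half-open.
        """
        first_midnight = dt.datetime.combine(self.start.date(), dt.time())
        lead = int((self.start - first_midnight).total_seconds()) // 60
        total = lead + self.n
        n_days = -(-total // MINUTES_PER_DAY)
        counts = np.full(n_days * MINUTES_PER_DAY, np.nan)
        recorded = np.zeros(n_days * MINUTES_PER_DAY, dtype=bool)
        excluded = np.zeros(n_days * MINUTES_PER_DAY, dtype=bool)
        counts[lead : lead + self.n] = self.counts
        recorded[lead : lead + self.n] = True
        excluded[lead : lead + self.n] = self.excluded
        valid = recorded & ~excluded
        counts = counts.reshape(n_days, MINUTES_PER_DAY)
        valid = valid.reshape(n_days, MINUTES_PER_DAY)
        dates = np.array(
            [first_midnight.date() + dt.timedelta(days=d) for d in range(n_days)]
        )
        return dates, counts, valid


@dataclass
class DiaryEntry:
    date: dt.date
    bed_time: dt.time | None
    wake_time: dt.time | None
    drinks: int
    present: bool = True

    def __post_init__(self) -> None:
        if self.drinks < 0:
            raise DataError(f"negative drink count on {self.date}")


@dataclass
class DiarySet:
    """Per-day sleep and alcohol diary for one participant."""

    participant_id: str
    entries: dict[dt.date, DiaryEntry] = field(default_factory=dict)

    def add(self, entry: DiaryEntry) -> None:
        if entry.date in self.entries:
            raise DataError(
                f"duplicate diary row for {self.participant_id} on {entry.date}"
            )
        self.entries[entry.date] = entry

    def drinks_on(self, date: dt.date) -> int | None:
        """Drinks recorded for ``date``; None when no diary entry exists."""
        entry = self.entries.get(date)
        return entry.drinks if entry is not None and entry.present else None

    @property
    def total_drinks(self) -> int:
        return sum(e.drinks for e in self.entries.values() if e.present)


@dataclass
class ParticipantManifest:
    participant_id: str
    discharge_date: dt.date
    sex: str  # {"female", "male", "not reported"}
    covariates: dict[str, object] = field(default_factory=dict)
    has_diary: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "not reported"):
            raise DataError(f"unrecognized sex category {self.sex!r}")


# ---------------------------------------------------------------------------
# epoch files


def read_epoch_file(
    path, dialect: EpochDialect = DEFAULT_DIALECT, participant_id: str | None = None
) -> EpochSeries:
    """Read an Actiware-style epoch export into an :class:`EpochSeries`.

    Rows flagged in the dialect's excluded column map to ``excluded=True``.
    Malformed rows (unparseable timestamps or counts) raise :class:`DataError`
    naming the first offending row rather than being dropped.
    """
    try:
        frame = pd.read_csv(
            path, sep=dialect.delimiter, skiprows=dialect.skip_rows, dtype=str
        )
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty epoch file") from None
    needed = {dialect.date_col, dialect.time_col, dialect.activity_col, dialect.excluded_col}
    missing = needed - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(frame) == 0:
        raise DataError(f"{path}: no epoch rows")

    stamps = pd.to_datetime(
        frame[dialect.date_col].str.strip() + " " + frame[dialect.time_col].str.strip(),
        format=f"{dialect.date_format} {dialect.time_format}",
        errors="coerce",
    )
    if stamps.isna().any():
        row = int(np.flatnonzero(stamps.isna().to_numpy())[0])
        raise DataError(f"{path}: unparseable timestamp at data row {row}")
    counts = pd.to_numeric(frame[dialect.activity_col], errors="coerce")
    if counts.isna().any():
        row = int(np.flatnonzero(counts.isna().to_numpy())[0])
        raise DataError(f"{path}: unparseable activity count at data row {row}")
    if (counts < 0).any():
        row = int(np.flatnonzero((counts < 0).to_numpy())[0])
        raise DataError(f"{path}: negative activity count at data row {row}")
    excl = pd.to_numeric(frame[dialect.excluded_col], errors="coerce").fillna(0) != 0

    deltas = stamps.diff().dt.total_seconds().to_numpy()[1:]
    bad = np.flatnonzero(deltas != EPOCH_SECONDS)
    if bad.size:
        raise DataError(
            f"{path}: non-monotonic or gapped timestamps at data row {int(bad[0]) + 1}"
        )
    pid = participant_id or str(path)
    return EpochSeries(
        participant_id=pid,
        start=stamps.iloc[0].to_pydatetime(),
        counts=counts.to_numpy(dtype=np.float64),
        excluded=excl.to_numpy(dtype=bool),
    )


def write_epoch_file(series: EpochSeries, path, dialect: EpochDialect = DEFAULT_DIALECT):
    """Write ``series`` as a delimited epoch export readable by :func:`read_epoch_file`."""
    stamps = series.timestamps()
    frame = pd.DataFrame(
        {
            dialect.date_col: stamps.strftime(dialect.date_format),
            dialect.time_col: stamps.strftime(dialect.time_format),
            dialect.activity_col: format_counts(series.counts),
            dialect.excluded_col: series.excluded.astype(int),
        }
    )
    frame.to_csv(path, sep=dialect.delimiter, index=False)
    return path


def format_counts(counts: np.ndarray) -> list[str]:
    # integral counts round-trip as integers; fractional ones keep full precision
    out = []
    for c in counts:
        out.append(str(int(c)) if float(c).is_integer() else repr(float(c)))
    return out


# ---------------------------------------------------------------------------
# diaries and manifest

DIARY_COLUMNS = ["participant_id", "date", "bed_time", "wake_time", "drinks"]


def read_diaries(path) -> dict[str, DiarySet]:
    """Read a diary table (one row per participant-day) into DiarySets keyed by participant."""
    frame = pd.read_csv(path, dtype=str)
    missing = set(DIARY_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing diary columns {sorted(missing)}")
    out: dict[str, DiarySet] = {}
    for _, row in frame.iterrows():
        pid = row["participant_id"]
        drinks = pd.to_numeric(row["drinks"], errors="coerce")
        if pd.isna(drinks) or drinks < 0 or drinks != int(drinks):
            raise DataError(f"{path}: bad drink count {row['drinks']!r} for {pid}")
        entry = DiaryEntry(
            date=dt.date.fromisoformat(row["date"]),
            bed_time=_parse_time(row.get("bed_time")),
            wake_time=_parse_time(row.get("wake_time")),
            drinks=int(drinks),
        )
        out.setdefault(pid, DiarySet(participant_id=pid)).add(entry)
    return out


def write_diaries(diaries: dict[str, DiarySet], path):
    rows = []
    for pid in sorted(diaries):
        for date in sorted(diaries[pid].entries):
            e = diaries[pid].entries[date]
            rows.append(
                {
                    "participant_id": pid,
                    "date": date.isoformat(),
                    "bed_time": e.bed_time.strftime("%H:%M") if e.bed_time else "",
                    "wake_time": e.wake_time.strftime("%H:%M") if e.wake_time else "",
                    "drinks": e.drinks,
                }
            )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)
    return path


def _parse_time(value) -> dt.time | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, str) and pd.isna(pd.Series([value]))[0]:
        return None
    parts = str(value).split(":")
    return dt.time(int(parts[0]), int(parts[1]))


MANIFEST_COLUMNS = ["participant_id", "discharge_date", "sex", "age"]


def read_manifest(path) -> dict[str, ParticipantManifest]:
    frame = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing manifest columns {sorted(missing)}")
    extra = [c for c in frame.columns if c not in ("participant_id", "discharge_date", "sex")]
    out: dict[str, ParticipantManifest] = {}
    for _, row in frame.iterrows():
        pid = row["participant_id"]
        if pid in out:
            raise DataError(f"{path}: duplicate manifest row for {pid}")
        out[pid] = ParticipantManifest(
            participant_id=pid,
            discharge_date=dt.date.fromisoformat(row["discharge_date"]),
            sex=row["sex"],
            covariates={c: row[c] for c in extra},
        )
    return out


def write_manifest(manifest: dict[str, ParticipantManifest], path):
    rows = []
    for pid in sorted(manifest):
        m = manifest[pid]
        row = {
            "participant_id": pid,
            "discharge_date": m.discharge_date.isoformat(),
            "sex": m.sex,
        }
        row.update(m.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
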