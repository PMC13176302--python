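import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from circact.io import EpochSeries
from circact.simulate import CohortSpec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n_participants=12, seed=42))


def square_wave_series(
    n_days: int = 1,
    wake_minute: int = 7 * 60,
    bed_minute: int = 23 * 60,
    active: float = 300.0,
    rest: float = 0.0,
    participant_id: str = "SQ",
    start: dt.datetime = dt.datetime(2024, 3, 1),
) -> EpochSeries:
    """Noiseless two-state day(s): rest before wake_minute and after bed_minute."""
    day = np.full(1440, rest)
    day[wake_minute:bed_minute] = active
    return EpochSeries(
        participant_id=participant_id,
        start=start,
        counts=np.tile(day, n_days),
        excluded=np.zeros(1440 * n_days, dtype=bool),
    )


@pytest.fixture
def square_day():
    return square_wave_series()
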