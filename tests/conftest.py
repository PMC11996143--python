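import numpy as np
import pandas as pd
import pytest

from wristrhythm import EpochCountSeries


def make_series(counts, epoch_s=30, start="2024-01-01", observed_fraction=None):
    counts = np.asarray(counts, dtype=float)
    times = pd.date_range(start, periods=len(counts), freq=f"{epoch_s}s")
    return EpochCountSeries(
        epoch_start_times=times,
        counts=counts,
        observed_fraction=observed_fraction,
        epoch_s=epoch_s,
    )


def rest_active_day(epoch_s=30, rest_level=20.0, active_level=100.0,
                    rest_start_h=23.0, rest_end_h=7.0):
    """One day of a square-wave profile: low counts 23:00-07:00, high otherwise."""
    H = 86400 // epoch_s
    hours = np.arange(H) * epoch_s / 3600.0
    in_rest = (hours >= rest_start_h) | (hours < rest_end_h)
    return np.where(in_rest, rest_level, active_level)


def screening_fixture_series(epoch_s=30):
    """7-day square-wave series with constructed wear defects.

    Day 1: 5 h missing (09:00-14:00)  -> invalid (>4 h nonwear).
    Day 2: 30 min missing inside the 23:00-07:00 sleep window (02:00-02:30)
           plus 2.5 h missing (12:00-14:30) -> invalid, 21 h of data.
    Day 3: 1.5 h missing (10:00-11:30) -> valid with 22.5 h of data (star).
    Days 0, 4, 5, 6: 2.5 h missing (12:00-14:30) -> valid, 21.5 h, no star.
    """
    day = rest_active_day(epoch_s)
    counts = np.tile(day, 7)
    eph = 3600 // epoch_s

    def cut(day_idx, start_h, dur_h):
        a = int((day_idx * 24 + start_h) * eph)
        counts[a : a + int(dur_h * eph)] = np.nan

    for d in (0, 4, 5, 6):
        cut(d, 12.0, 2.5)
    cut(1, 9.0, 5.0)
    cut(2, 2.0, 0.5)
    cut(2, 12.0, 2.5)
    cut(3, 10.0, 1.5)
    return make_series(counts, epoch_s=epoch_s)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
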