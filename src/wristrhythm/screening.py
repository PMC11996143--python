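"""Nonwear detection, main-sleep-period estimation, and valid-day screening.

A day is valid when it has at most 4 h of nonwear and no nonwear inside the
main sleep period; a recording is adequate when it contains at least 3
consecutive valid days. Days with at least 22 h of worn data earn a "star"
(the encouragement feedback shown to wearers). Invalid days and nonwear
epochs are censored — marked missing, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .series import EpochCountSeries, circular_window_means, mean_daily_profile

__all__ = [
    "WearMask",
    "DayScreeningReport",
    "RecordingScreeningReport",
    "detect_nonwear",
    "estimate_main_sleep_period",
    "screen_recording",
]

MAX_NONWEAR_HOURS = 4.0
STAR_HOURS = 22.0
MIN_VALID_RUN_DAYS = 3
DEFAULT_MIN_RUN_MINUTES = 90.0
DEFAULT_SLEEP_WINDOW_HOURS = 8.0


@dataclass
class WearMask:
    """Per-epoch worn flag aligned to an EpochCountSeries."""

    worn: np.ndarray
    epoch_s: int

    def __post_init__(self) -> None:
        self.worn = np.asarray(self.worn, dtype=bool)

    def check_aligned(self, series: EpochCountSeries) -> None:
        if len(self.worn) != series.n_epochs or self.epoch_s != series.epoch_s:
            raise ValueError("wear mask is not aligned to the count series")


@dataclass
class DayScreeningReport:
    calendar_day: str
    nonwear_hours: float
    sleep_period_window: tuple[float, float]
    sleep_period_nonwear: bool
    data_hours: float
    valid: bool
    star_awarded: bool


@dataclass
class RecordingScreeningReport:
    days: list[DayScreeningReport]
    n_valid_days: int
    longest_consecutive_valid_run: int
    adequate: bool
    recording_length_days: int
    worn_days_real: float

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def detect_nonwear(
    series: EpochCountSeries,
    min_run_minutes: float = DEFAULT_MIN_RUN_MINUTES,
    count_threshold: float | None = None,
) -> WearMask:
    """Flag nonwear as long runs of near-zero counts plus all missing epochs.

    Epochs in any maximal run of at least ``min_run_minutes`` whose counts are
    all at or below ``count_threshold`` are not-worn. Missing epochs are
    not-worn by definition and extend adjacent low-count runs. The default
    threshold is 1% of the median positive count, the usual count-based
    actigraphy convention.
    """
    if series.n_epochs == 0:
        raise ValueError("empty series")
    counts = series.counts
    if count_threshold is None:
        positive = counts[series.observed & (counts > 0)]
        count_threshold = 0.01 * float(np.median(positive)) if positive.size else 0.0

    low = series.missing | (np.nan_to_num(counts, nan=0.0) <= count_threshold)
    min_run_epochs = int(np.ceil(min_run_minutes * 60.0 / series.epoch_s))

    worn = series.observed.copy()
    # run-length encode the low/missing indicator
    edges = np.flatnonzero(np.diff(low.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(low)]])
    for a, b in zip(starts, ends):
        if low[a] and (b - a) >= min_run_epochs:
            worn[a:b] = False
    return WearMask(worn=worn, epoch_s=series.epoch_s)


def estimate_main_sleep_period(
    series: EpochCountSeries,
    window_hours: float = DEFAULT_SLEEP_WINDOW_HOURS,
    mask: WearMask | None = None,
) -> tuple[float, float]:
    """Lowest-mean circular window of the average 24-h profile.

    Returns (start_h, end_h) clock hours; ties broken by earliest start.
    Only worn (or at least observed) epochs contribute to the profile.
    """
    if series.n_epochs * series.epoch_s < 86400:
        raise ValueError("need at least 24 h of data to place the sleep period")
    if mask is not None:
        mask.check_aligned(series)
        work = series.with_counts(np.where(mask.worn, series.counts, np.nan))
    else:
        work = series
    profile, _ = mean_daily_profile(work)
    window_bins = int(round(window_hours * 3600 / series.epoch_s))
    means = circular_window_means(profile, window_bins)
    if not np.any(np.isfinite(means)):
        raise ValueError("no observed data to estimate the sleep period")
    finite_min = np.nanmin(means)
    start_bin = int(np.flatnonzero(means == finite_min)[0])
    start_h = start_bin * series.epoch_s / 3600.0
    end_h = (start_h + window_hours) % 24.0
    return start_h, end_h


def _longest_true_run(flags: list[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


@dataclass
class ScreeningResult:
    report: RecordingScreeningReport
    censored: EpochCountSeries
    mask: WearMask = field(repr=False, default=None)  # type: ignore[assignment]


def screen_recording(
    series: EpochCountSeries,
    mask: WearMask,
    sleep_window: tuple[float, float],
    max_nonwear_hours: float = MAX_NONWEAR_HOURS,
    star_hours: float = STAR_HOURS,
    min_valid_run_days: int = MIN_VALID_RUN_DAYS,
) -> ScreeningResult:
    """Apply valid-day and adequacy rules; censor invalid data.

    Per calendar day: ``data_hours`` is the worn time, ``nonwear_hours`` the
    remainder of the 24-h day (epochs outside the recording span count as
    nonwear, so partial first/last days are screened like any other). A day
    is valid iff nonwear_hours <= ``max_nonwear_hours`` and no nonwear (or
    out-of-recording time) falls inside that day's sleep-period window. The
    censored series keeps every retained count unchanged and marks nonwear
    epochs and whole invalid days missing.
    """
    mask.check_aligned(series)
    start_h, end_h = sleep_window
    window_len_h = (end_h - start_h) % 24.0
    if window_len_h == 0:
        window_len_h = 24.0

    eph = series.epochs_per_hour
    day_keys = series.day_keys()
    days = pd.DatetimeIndex(sorted(set(day_keys)))

    # circular time-of-day membership: the sleep period of a calendar day is
    # the clock window intersected with that day, so a window wrapping
    # midnight contributes its late-evening and early-morning portions to the
    # same day and every day is screened self-contained
    tod_h = series.tod_bins() * series.epoch_s / 3600.0
    if start_h <= end_h and window_len_h < 24.0:
        in_clock_window = (tod_h >= start_h) & (tod_h < end_h)
    else:
        in_clock_window = (tod_h >= start_h) | (tod_h < end_h)
    expected_epochs = int(round(window_len_h * eph))

    day_reports: list[DayScreeningReport] = []
    censored_counts = np.where(mask.worn, series.counts, np.nan)
    for day in days:
        in_day = np.asarray(day_keys == day)
        data_hours = float(np.sum(mask.worn[in_day]) / eph)
        nonwear_hours = 24.0 - data_hours

        in_window = in_day & in_clock_window
        covered = int(np.sum(in_window))
        sleep_nonwear = bool(
            covered < expected_epochs or np.any(~mask.worn[in_window])
        )

        valid = (nonwear_hours <= max_nonwear_hours) and not sleep_nonwear
        if not valid:
            censored_counts[np.asarray(in_day)] = np.nan
        day_reports.append(
            DayScreeningReport(
                calendar_day=str(day.date()),
                nonwear_hours=nonwear_hours,
                sleep_period_window=(start_h, end_h),
                sleep_period_nonwear=sleep_nonwear,
                data_hours=data_hours,
                valid=valid,
                star_awarded=data_hours >= star_hours,
            )
        )

    valid_flags = [d.valid for d in day_reports]
    longest = _longest_true_run(valid_flags)
    worn_hours_total = float(np.sum(mask.worn) / eph)
    report = RecordingScreeningReport(
        days=day_reports,
        n_valid_days=int(sum(valid_flags)),
        longest_consecutive_valid_run=longest,
        adequate=longest >= min_valid_run_days,
        recording_length_days=int(
            sum(bool(np.any(mask.worn[np.asarray(day_keys == d)])) for d in days)
        ),
        worn_days_real=worn_hours_total / 24.0,
    )
    observed_fraction = np.where(np.isnan(censored_counts), 0.0, series.observed_fraction)
    censored = EpochCountSeries(
        epoch_start_times=series.epoch_start_times,
        counts=censored_counts,
        observed_fraction=observed_fraction,
        epoch_s=series.epoch_s,
    )
    return ScreeningResult(report=report, censored=censored, mask=mask)
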