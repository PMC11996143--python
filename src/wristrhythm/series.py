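"""Epoch-level activity count series.

The central in-memory container shared by every pipeline stage: a regular
grid of fixed-length epochs (default 30 s) with a nonnegative activity count
and an observed-sample fraction per epoch. Missing epochs carry NaN counts
and are never imputed anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochCountSeries",
    "read_counts_csv",
    "write_counts_csv",
    "mean_daily_profile",
    "circular_window_means",
]

#: epochs with fewer than this fraction of expected raw samples are missing
DEFAULT_COMPLETENESS_THRESHOLD = 0.5


@dataclass
class EpochCountSeries:
    """Activity counts on a regular epoch grid aligned to the local clock.

    Parameters
    ----------
    epoch_start_times
        Start times of each epoch (timezone-naive local clock) on a regular
        grid with spacing ``epoch_s`` seconds, aligned to clock boundaries.
    counts
        Nonnegative activity count per epoch; NaN marks a missing epoch.
    observed_fraction
        Fraction of expected raw samples observed in each epoch, in [0, 1].
        Series built directly at epoch level use 1.0 (observed) / 0.0 (missing).
    epoch_s
        Epoch length in seconds; must divide the day evenly.
    """

    epoch_start_times: pd.DatetimeIndex
    counts: np.ndarray
    observed_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_s: int = 30

    def __post_init__(self) -> None:
        self.epoch_start_times = pd.DatetimeIndex(self.epoch_start_times)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.observed_fraction is None:
            self.observed_fraction = np.where(np.isnan(self.counts), 0.0, 1.0)
        self.observed_fraction = np.asarray(self.observed_fraction, dtype=float)
        n = len(self.epoch_start_times)
        if n == 0:
            raise ValueError("empty epoch series")
        if len(self.counts) != n or len(self.observed_fraction) != n:
            raise ValueError("counts/observed_fraction length must match epoch grid")
        if 86400 % self.epoch_s != 0:
            raise ValueError(f"epoch_s={self.epoch_s} must divide the 86400-s day")
        if n > 1:
            deltas = np.diff(self.epoch_start_times.asi8) / 1e9
            if not np.allclose(deltas, self.epoch_s):
                raise ValueError("epoch grid spacing must equal epoch_s exactly")
        obs = ~np.isnan(self.counts)
        if np.any(self.counts[obs] < 0):
            raise ValueError("counts must be nonnegative where observed")
        if np.any((self.observed_fraction < 0) | (self.observed_fraction > 1)):
            raise ValueError("observed_fraction must lie in [0, 1]")

    # -- basic geometry -------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_s

    @property
    def epochs_per_hour(self) -> float:
        return 3600.0 / self.epoch_s

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing epochs (NaN count)."""
        return np.isnan(self.counts)

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    def tod_bins(self) -> np.ndarray:
        """Time-of-day bin index (0 .. epochs_per_day-1) of each epoch."""
        secs = (
            self.epoch_start_times.asi8 - self.epoch_start_times.normalize().asi8
        ) / 1e9
        return (secs / self.epoch_s).astype(np.int64)

    def day_keys(self) -> pd.DatetimeIndex:
        """Calendar day (local midnight) of each epoch."""
        return self.epoch_start_times.normalize()

    def hours_since_midnight0(self) -> np.ndarray:
        """Continuous clock time in hours since the first epoch's midnight."""
        t0 = self.epoch_start_times[0].normalize()
        return (self.epoch_start_times.asi8 - t0.value) / 3.6e12

    def with_counts(self, counts: np.ndarray) -> "EpochCountSeries":
        """Copy of the series with replaced counts (same grid)."""
        return replace(self, counts=np.asarray(counts, dtype=float))

    def observed_span_hours(self) -> float:
        """Clock span between first and last observed epoch, in hours."""
        idx = np.flatnonzero(self.observed)
        if idx.size == 0:
            return 0.0
        return (idx[-1] - idx[0] + 1) * self.epoch_s / 3600.0


def write_counts_csv(series: EpochCountSeries, path) -> None:
    """Write a series as delimited text: epoch_start_iso,count,observed_fraction."""
    df = pd.DataFrame(
        {
            "epoch_start_iso": series.epoch_start_times.strftime("%Y-%m-%dT%H:%M:%S"),
            "count": series.counts,
            "observed_fraction": series.observed_fraction,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_counts_csv(path, epoch_s: int | None = None) -> EpochCountSeries:
    """Read a series written by :func:`write_counts_csv`.

    The epoch length is inferred from the grid unless given explicitly.
    """
    df = pd.read_csv(path)
    required = {"epoch_start_iso", "count", "observed_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    times = pd.DatetimeIndex(pd.to_datetime(df["epoch_start_iso"]))
    if epoch_s is None:
        if len(times) < 2:
            raise ValueError("cannot infer epoch length from a single epoch")
        epoch_s = int(round((times[1] - times[0]).total_seconds()))
    return EpochCountSeries(
        epoch_start_times=times,
        counts=df["count"].to_numpy(dtype=float),
        observed_fraction=df["observed_fraction"].to_numpy(dtype=float),
        epoch_s=epoch_s,
    )


def mean_daily_profile(series: EpochCountSeries) -> tuple[np.ndarray, np.ndarray]:
    """Average 24-h profile at native epoch resolution.

    Returns ``(profile, n_obs)`` where ``profile[h]`` is the mean count over
    the observed epochs falling in time-of-day bin ``h`` (NaN when no day
    contributes) and ``n_obs[h]`` the number of observed epochs in that bin.
    """
    H = series.epochs_per_day
    bins = series.tod_bins()
    obs = series.observed
    sums = np.bincount(bins[obs], weights=series.counts[obs], minlength=H)
    n = np.bincount(bins[obs], minlength=H).astype(float)
    with np.errstate(invalid="ignore"):
        profile = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return profile, n


def circular_window_means(profile: np.ndarray, window_bins: int) -> np.ndarray:
    """Mean of ``profile`` over each circular window of ``window_bins`` bins.

    NaN bins are skipped inside a window; a window with no finite bin yields
    NaN. Entry ``k`` is the mean of the window starting at bin ``k``.
    """
    H = len(profile)
    if not 1 <= window_bins <= H:
        raise ValueError("window length must be between 1 bin and one full day")
    finite = np.isfinite(profile)
    vals = np.where(finite, profile, 0.0)
    ext_v = np.concatenate([vals, vals[: window_bins - 1]]) if window_bins > 1 else vals
    ext_c = (
        np.concatenate([finite, finite[: window_bins - 1]])
        if window_bins > 1
        else finite
    )
    cv = np.concatenate([[0.0], np.cumsum(ext_v)])
    cc = np.concatenate([[0], np.cumsum(ext_c)])
    sums = cv[window_bins:] - cv[:-window_bins] if window_bins > 1 else vals
    cnts = cc[window_bins:] - cc[:-window_bins] if window_bins > 1 else finite.astype(int)
    sums = np.asarray(sums, dtype=float)[:H]
    cnts = np.asarray(cnts, dtype=float)[:H]
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
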