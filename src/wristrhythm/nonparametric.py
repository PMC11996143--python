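"""Nonparametric 24-h rest-activity rhythm metrics.

All metrics operate on the full-resolution censored series (no hourly
subsampling):

* **Interdaily stability (IS)** — ratio of the variance of the mean 24-h
  profile to the total variance; 1 for a perfectly repeated daily pattern,
  approximately 1/n_days for structureless noise.
* **Intradaily variability (IV)** — normalized mean squared successive
  difference, computable over a family of numerator timescales tau (window
  means of tau minutes) while the denominator (variance of the
  native-resolution observed series) is held constant across timescales.
  Higher values mean more fragmented rhythms.
* **Relative amplitude (RA)** — (M10 - L5)/(M10 + L5) where M10 / L5 are the
  means of the most-active 10-h and least-active 5-h circular windows of the
  average daily profile.

Missing epochs are excluded everywhere; IV never differences across a
censored gap.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .series import EpochCountSeries, circular_window_means, mean_daily_profile

__all__ = [
    "NonparametricMetrics",
    "interdaily_stability",
    "intradaily_variability",
    "iv_family",
    "relative_amplitude",
    "compute_nonparametric_metrics",
    "DEFAULT_IV_TAUS",
]

DEFAULT_IV_TAUS = tuple(range(5, 65, 5))  # minutes
M10_HOURS = 10.0
L5_HOURS = 5.0


@dataclass
class NonparametricMetrics:
    IS: float
    RA: float
    M10: float
    L5: float
    M10_onset_h: float
    L5_onset_h: float
    IV_by_tau: dict[int, float]
    n_days_used: int
    n_epochs_used: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["IV_by_tau"] = {str(k): v for k, v in self.IV_by_tau.items()}
        return d


def interdaily_stability(series: EpochCountSeries) -> float:
    """IS at native resolution with per-bin observation weights.

    IS = [sum_h n_h (xbar_h - xbar)^2 / sum_h n_h] / [sum_i (x_i - xbar)^2 / N]
    where xbar_h is the mean over days of time-of-day bin h, n_h the number of
    observed days contributing to bin h, and the denominator is the population
    variance of all N observed epochs. Bins with no observations drop out.
    """
    obs = series.observed
    x = series.counts[obs]
    if x.size < 2:
        raise ValueError("too few observed epochs")
    xbar = x.mean()
    total = float(np.mean((x - xbar) ** 2))
    if total == 0.0:
        raise ValueError("degenerate: zero total variance")
    bins = series.tod_bins()[np.asarray(obs)]
    H = series.epochs_per_day
    n_h = np.bincount(bins, minlength=H).astype(float)
    sums = np.bincount(bins, weights=x, minlength=H)
    nz = n_h > 0
    means = sums[nz] / n_h[nz]
    between = float(np.sum(n_h[nz] * (means - xbar) ** 2) / np.sum(n_h[nz]))
    return between / total


def _window_means_and_validity(
    series: EpochCountSeries, width_epochs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping window means from the series start; a window is usable
    only if fully inside the series with no missing epoch."""
    n_win = series.n_epochs // width_epochs
    trimmed = series.counts[: n_win * width_epochs].reshape(n_win, width_epochs)
    usable = ~np.isnan(trimmed).any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = trimmed.mean(axis=1)
    return means, usable


def intradaily_variability(series: EpochCountSeries, tau_minutes: float) -> float:
    """IV at numerator timescale ``tau_minutes``.

    Numerator: mean squared successive difference of non-overlapping
    tau-minute window means; windows containing any missing epoch are
    dropped, and only temporally adjacent window pairs are differenced (a
    censored gap breaks the chain). Denominator: population variance of the
    native-resolution observed series, identical for every tau.
    """
    epoch_min = series.epoch_s / 60.0
    width = tau_minutes / epoch_min
    if tau_minutes < epoch_min or abs(width - round(width)) > 1e-9:
        raise ValueError(
            f"tau={tau_minutes} min must be a multiple of the {epoch_min:g}-min epoch"
        )
    width_epochs = int(round(width))
    obs = series.counts[series.observed]
    if obs.size < 2:
        raise ValueError("too few observed epochs")
    denom = float(np.mean((obs - obs.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("degenerate: zero variance")

    means, usable = _window_means_and_validity(series, width_epochs)
    pair_ok = usable[:-1] & usable[1:]
    if int(pair_ok.sum()) < 1 or int(usable.sum()) < 2:
        raise ValueError("fewer than 2 usable windows for IV")
    d = means[1:][pair_ok] - means[:-1][pair_ok]
    numerator = float(np.mean(d**2))
    return numerator / denom


def iv_family(
    series: EpochCountSeries, taus_minutes=DEFAULT_IV_TAUS
) -> dict[int, float]:
    """IV at each timescale in ``taus_minutes`` (default 5..60 by 5)."""
    return {int(tau): intradaily_variability(series, tau) for tau in taus_minutes}


def relative_amplitude(
    series: EpochCountSeries,
) -> tuple[float, float, float, float, float]:
    """Returns (RA, M10, L5, M10_onset_h, L5_onset_h).

    M10/L5 search every circular window position at native epoch step on the
    average daily profile; ties take the earliest clock start. A flat zero
    profile yields RA = 0 with a warning.
    """
    profile, n_obs = mean_daily_profile(series)
    if not np.any(n_obs > 0):
        raise ValueError("no observed epochs")
    bins_m10 = int(round(M10_HOURS * 3600 / series.epoch_s))
    bins_l5 = int(round(L5_HOURS * 3600 / series.epoch_s))
    m10_means = circular_window_means(profile, bins_m10)
    l5_means = circular_window_means(profile, bins_l5)
    m10_val = float(np.nanmax(m10_means))
    l5_val = float(np.nanmin(l5_means))
    m10_start = int(np.flatnonzero(m10_means == m10_val)[0])
    l5_start = int(np.flatnonzero(l5_means == l5_val)[0])
    h_per_bin = series.epoch_s / 3600.0
    if m10_val + l5_val > 0:
        ra = (m10_val - l5_val) / (m10_val + l5_val)
    else:
        warnings.warn("M10 + L5 = 0; relative amplitude defined as 0", RuntimeWarning)
        ra = 0.0
    return ra, m10_val, l5_val, m10_start * h_per_bin, l5_start * h_per_bin


def compute_nonparametric_metrics(
    series: EpochCountSeries, taus_minutes=DEFAULT_IV_TAUS
) -> NonparametricMetrics:
    """All nonparametric metrics for one censored recording."""
    ra, m10, l5, m10_on, l5_on = relative_amplitude(series)
    obs = series.observed
    return NonparametricMetrics(
        IS=interdaily_stability(series),
        RA=ra,
        M10=m10,
        L5=l5,
        M10_onset_h=m10_on,
        L5_onset_h=l5_on,
        IV_by_tau=iv_family(series, taus_minutes),
        n_days_used=len(set(series.day_keys()[np.asarray(obs)])),
        n_epochs_used=int(obs.sum()),
    )
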