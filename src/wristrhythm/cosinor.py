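"""Sigmoidally transformed extended cosine model for 24-h activity rhythms.

The fitted curve is

    y(t) = min_level + amplitude * logistic(beta * (cos(2*pi*(t - phi)/24) - alpha))

with a fixed 24-h period. The logistic transform lets the model take
square-wave-like shapes (alpha controls the fraction of the day spent active,
beta the steepness of the rest/active transitions). Rhythm robustness is
summarised by a pseudo-F statistic (extra sum of squares against the
mean-only model); activity onset and offset are the clock times at which the
curve crosses the middle of its modelled range (up-mesor / down-mesor).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .series import EpochCountSeries, circular_window_means, mean_daily_profile

__all__ = [
    "ExtendedCosineFit",
    "sigmoid_cosine",
    "fit_extended_cosine",
    "mesor_crossings",
]

N_PARAMS = 5  # min_level, amplitude, acrophase, alpha, beta

ALPHA_BOUND = 0.999
BETA_BOUNDS = (0.1, 50.0)


def sigmoid_cosine(
    t_h: np.ndarray,
    min_level: float,
    amplitude: float,
    acrophase_h: float,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Evaluate the sigmoid-transformed cosine curve at clock hours ``t_h``."""
    c = np.cos(2.0 * np.pi * (np.asarray(t_h, dtype=float) - acrophase_h) / 24.0)
    return min_level + amplitude * expit(beta * (c - alpha))


@dataclass
class ExtendedCosineFit:
    """Fitted extended-cosine parameters and derived rhythm measures."""

    min_level: float
    amplitude: float
    acrophase_h: float
    alpha: float
    beta_steepness: float
    rss_model: float
    rss_null: float
    n_obs: int
    pseudo_F: float
    up_mesor_h: float
    down_mesor_h: float
    converged: bool

    def predict(self, t_h: np.ndarray) -> np.ndarray:
        return sigmoid_cosine(
            t_h,
            self.min_level,
            self.amplitude,
            self.acrophase_h,
            self.alpha,
            self.beta_steepness,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _residuals_and_jac(t_h: np.ndarray, y: np.ndarray):
    two_pi_24 = 2.0 * np.pi / 24.0

    def resid(p):
        return sigmoid_cosine(t_h, *p) - y

    def jac(p):
        _, amp, phi, alpha, beta = p
        theta = two_pi_24 * (t_h - phi)
        c = np.cos(theta)
        s = expit(beta * (c - alpha))
        sp = s * (1.0 - s)
        J = np.empty((t_h.size, N_PARAMS))
        J[:, 0] = 1.0
        J[:, 1] = s
        J[:, 2] = amp * sp * beta * np.sin(theta) * two_pi_24
        J[:, 3] = -amp * sp * beta
        J[:, 4] = amp * sp * (c - alpha)
        return J

    return resid, jac


def _initial_acrophase(series: EpochCountSeries) -> float:
    """Peak hour of the 1-h smoothed mean daily profile."""
    profile, _ = mean_daily_profile(series)
    bins_1h = max(1, int(round(3600 / series.epoch_s)))
    smoothed = circular_window_means(profile, bins_1h)
    if not np.any(np.isfinite(smoothed)):
        return 14.0
    k = int(np.nanargmax(smoothed))
    # window starting at k: centre it
    return ((k + bins_1h / 2.0) * series.epoch_s / 3600.0) % 24.0


def fit_extended_cosine(
    series: EpochCountSeries,
    seed: int = 0,
    n_restarts: int = 8,
    min_span_days: float = 3.0,
) -> ExtendedCosineFit:
    """Fit the extended cosine model to a censored epoch-count series.

    Missing epochs are excluded from the loss (censored, never imputed).
    A multi-start bounded least-squares search (acrophase jittered +/- 3 h
    across restarts, controlled by ``seed``) guards against the logistic
    plateau; the restart with the lowest residual sum of squares wins.
    """
    obs = series.observed
    y = series.counts[obs]
    t_h = series.hours_since_midnight0()[np.asarray(obs)]
    if series.observed_span_hours() < min_span_days * 24.0 - series.epoch_s / 3600.0:
        raise ValueError(
            f"series spans fewer than {min_span_days:g} days of observed data; "
            "screening adequacy required before fitting"
        )
    if y.size < 4 * N_PARAMS:
        raise ValueError("too few observed epochs to fit 5 parameters")
    ystd = float(np.std(y))
    if ystd == 0.0:
        raise ValueError("degenerate: no rhythm variance")

    ylo, yhi = np.percentile(y, [5, 95])
    amp0 = max(yhi - ylo, 1e-6)
    phi_base = _initial_acrophase(series)
    ymax = float(np.max(y))
    lower = np.array([0.0, 1e-9, phi_base - 12.0, -ALPHA_BOUND, BETA_BOUNDS[0]])
    upper = np.array(
        [ymax + 1.0, 10.0 * (ymax - np.min(y)) + 1.0, phi_base + 12.0, ALPHA_BOUND, BETA_BOUNDS[1]]
    )

    resid, jac = _residuals_and_jac(t_h, y)
    rng = np.random.default_rng(seed)
    jitters = np.concatenate([[0.0], rng.uniform(-3.0, 3.0, size=max(0, n_restarts - 1))])

    best = None
    for dphi in jitters:
        x0 = np.array([max(ylo, 0.0), amp0, phi_base + dphi, 0.0, 2.0])
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        res = least_squares(
            resid,
            x0,
            jac=jac,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res

    p = best.x
    rss_model = float(np.sum(resid(p) ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    denom = rss_model / (n - N_PARAMS)
    pseudo_F = float(((rss_null - rss_model) / (N_PARAMS - 1)) / denom) if denom > 0 else math.inf

    phi = float(p[2]) % 24.0
    fit = ExtendedCosineFit(
        min_level=float(p[0]),
        amplitude=float(p[1]),
        acrophase_h=phi,
        alpha=float(p[3]),
        beta_steepness=float(p[4]),
        rss_model=rss_model,
        rss_null=rss_null,
        n_obs=int(n),
        pseudo_F=max(pseudo_F, 0.0),
        up_mesor_h=math.nan,
        down_mesor_h=math.nan,
        converged=bool(best.success),
    )
    fit.up_mesor_h, fit.down_mesor_h = mesor_crossings(fit)
    return fit


def mesor_crossings(fit: ExtendedCosineFit) -> tuple[float, float]:
    """Clock times where the fitted curve crosses min_level + amplitude/2.

    The logistic equals 1/2 exactly where cos(2*pi*(t - phi)/24) = alpha, so
    the crossings are phi -/+ (24/2pi) * arccos(alpha) reduced mod 24; the
    ascending crossing (before the peak) is the up-mesor.
    """
    if abs(fit.alpha) >= 1.0:
        raise ValueError("no mesor crossing: |alpha| >= 1")
    if not fit.amplitude > 0:
        raise ValueError("no mesor crossing: amplitude must be positive")
    half_width_h = (24.0 / (2.0 * np.pi)) * math.acos(fit.alpha)
    up = (fit.acrophase_h - half_width_h) % 24.0
    down = (fit.acrophase_h + half_width_h) % 24.0
    return up, down
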