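"""Synthetic rest-activity data with known ground truth.

Generates multi-day epoch-count series (and optionally raw 50 Hz triaxial
streams) whose 24-h mean structure is the same sigmoid-transformed cosine the
fitting module estimates, with optional rhythm fragmentation, noise, and
nonwear gaps:

* **Mean curve** — sigmoid-cosine with parameters (min_level, amplitude,
  acrophase, alpha, beta).
* **Fragmentation** — a two-state rest/active Markov chain whose exit hazards
  are modulated by the normalised mean curve, so the chain tends to be active
  when the curve is high. Mean dwell times (minutes) set the switching
  timescale: shorter dwells produce more fragmented series, which is exactly
  what multi-timescale intradaily variability is designed to detect.
* **Noise** — additive Gaussian and/or multiplicative lognormal; counts are
  truncated at zero.
* **Nonwear** — inserted gaps become missing epochs (never zero counts).

Everything is driven by one seeded generator per call; equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.special import expit

from .series import EpochCountSeries
from .cosinor import sigmoid_cosine

__all__ = [
    "SimulationConfig",
    "simulate_epoch_series",
    "simulate_raw_recording",
    "simulate_cohort_table",
    "IV_TAUS_MIN",
]

IV_TAUS_MIN = tuple(range(5, 65, 5))


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated recording.

    ``nonwear_gaps`` is a list of ``(day_index, start_clock_h, duration_h)``
    tuples; the covered epochs become missing. ``dwell_rest_min`` /
    ``dwell_active_min`` of None disables fragmentation (state always
    active). ``raw_duration_s`` limits the raw-mode stream length (raw files
    at 50 Hz are large; epoch-mode output always covers ``n_days``).
    """

    n_days: int = 7
    epoch_s: int = 30
    start: datetime = datetime(2024, 1, 1, 0, 0, 0)
    min_level: float = 10.0
    amplitude: float = 100.0
    acrophase_h: float = 14.0
    alpha: float = 0.2
    beta_steepness: float = 4.0
    dwell_rest_min: float | None = None
    dwell_active_min: float | None = None
    noise_sd: float = 0.0
    lognorm_sigma: float = 0.0
    nonwear_gaps: list[tuple[int, float, float]] = field(default_factory=list)
    rate_hz: float = 50.0
    carrier_hz: float = 1.5
    raw_duration_s: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.epoch_s <= 0 or 86400 % self.epoch_s != 0:
            raise ValueError("epoch_s must be positive and divide the day")
        if not -0.999 < self.alpha < 0.999:
            raise ValueError("alpha must lie in (-0.999, 0.999)")
        if not 0.1 <= self.beta_steepness <= 50:
            raise ValueError("beta_steepness outside (0.1, 50)")
        if self.amplitude <= 0 or self.min_level < 0:
            raise ValueError("amplitude must be > 0 and min_level >= 0")
        if (self.dwell_rest_min is None) != (self.dwell_active_min is None):
            raise ValueError("set both dwell times or neither")
        for d in (self.dwell_rest_min, self.dwell_active_min):
            if d is not None and d <= 0:
                raise ValueError("dwell times must be positive minutes")
        if self.noise_sd < 0 or self.lognorm_sigma < 0:
            raise ValueError("noise scales must be nonnegative")
        for gap in self.nonwear_gaps:
            day, start_h, dur_h = gap
            if dur_h <= 0 or not 0 <= start_h < 24 or not 0 <= day < self.n_days:
                raise ValueError(f"invalid nonwear gap {gap}")


def _state_path(
    p_exit_rest: np.ndarray,
    p_exit_active: np.ndarray,
    rng: np.random.Generator,
    init_active: bool,
) -> np.ndarray:
    """Exact two-state Markov path with time-varying exit probabilities.

    Per-state Bernoulli draws are materialised up front; the path is then a
    walk over transition indices (searchsorted), so cost scales with the
    number of transitions rather than epochs.
    """
    n = len(p_exit_rest)
    u_rest = rng.random(n)
    u_active = rng.random(n)
    hit_r = np.flatnonzero(u_rest < p_exit_rest)
    hit_a = np.flatnonzero(u_active < p_exit_active)
    state = np.empty(n, dtype=bool)
    i = 0
    active = init_active
    while i < n:
        hits = hit_a if active else hit_r
        k = np.searchsorted(hits, i)
        j = int(hits[k]) if k < len(hits) else n - 1
        state[i : j + 1] = active
        i = j + 1
        active = not active
    return state


def simulate_epoch_series(config: SimulationConfig) -> tuple[EpochCountSeries, dict]:
    """Simulate an epoch-count series; returns (series, ground_truth).

    counts = state(t) * mean_curve(t) * lognormal_noise + gaussian_noise,
    truncated at 0; nonwear gaps become missing epochs. The ground-truth dict
    carries the curve parameters, the clean curve, the state path, and the
    noise-free target profile ``state * curve``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H = 86400 // config.epoch_s
    n = config.n_days * H
    times = pd.date_range(pd.Timestamp(config.start), periods=n, freq=f"{config.epoch_s}s")
    t0 = times[0].normalize()
    t_h = (times.asi8 - t0.value) / 3.6e12

    curve = sigmoid_cosine(
        t_h,
        config.min_level,
        config.amplitude,
        config.acrophase_h,
        config.alpha,
        config.beta_steepness,
    )

    if config.dwell_rest_min is not None:
        # normalised curve in (0,1) modulates the exit hazards so that, with
        # equal dwell times, the stationary active probability tracks it
        c = expit(
            config.beta_steepness
            * (np.cos(2 * np.pi * (t_h - config.acrophase_h) / 24.0) - config.alpha)
        )
        lam_r = 2.0 * c / (config.dwell_rest_min * 60.0)
        lam_a = 2.0 * (1.0 - c) / (config.dwell_active_min * 60.0)
        p_exit_rest = 1.0 - np.exp(-lam_r * config.epoch_s)
        p_exit_active = 1.0 - np.exp(-lam_a * config.epoch_s)
        init_active = bool(rng.random() < c[0])
        state = _state_path(p_exit_rest, p_exit_active, rng, init_active)
    else:
        state = np.ones(n, dtype=bool)

    target = state * curve
    counts = target.copy()
    if config.lognorm_sigma > 0:
        z = rng.standard_normal(n)
        counts = counts * np.exp(config.lognorm_sigma * z - config.lognorm_sigma**2 / 2)
    if config.noise_sd > 0:
        counts = counts + config.noise_sd * rng.standard_normal(n)
    counts = np.maximum(counts, 0.0)

    observed_fraction = np.ones(n)
    for day, start_h, dur_h in config.nonwear_gaps:
        a = int(round((day * 24 + start_h) * 3600 / config.epoch_s))
        b = int(round((day * 24 + start_h + dur_h) * 3600 / config.epoch_s))
        b = min(b, n)
        counts[a:b] = np.nan
        observed_fraction[a:b] = 0.0

    series = EpochCountSeries(
        epoch_start_times=times,
        counts=counts,
        observed_fraction=observed_fraction,
        epoch_s=config.epoch_s,
    )
    truth = {
        "params": {
            "min_level": config.min_level,
            "amplitude": config.amplitude,
            "acrophase_h": config.acrophase_h,
            "alpha": config.alpha,
            "beta_steepness": config.beta_steepness,
        },
        "curve": curve,
        "state": state,
        "target": target,
        "sleep_midpoint_h": (config.acrophase_h + 12.0) % 24.0,
    }
    return series, truth


def simulate_raw_recording(config: SimulationConfig, path) -> dict:
    """Write a raw 50 Hz triaxial stream whose epoch counts track the target.

    The x axis carries a sinusoid at ``carrier_hz`` (inside the default
    movement passband) whose amplitude is piecewise-constant per epoch and
    proportional to the target count profile; the z axis carries unit
    gravity (out of band). For a sinusoid of amplitude A the mean rectified
    filtered norm is 2A/pi, so A = target_count * pi / (2 * epoch_s) makes
    the computed counts match the target up to filter edge effects.

    Returns a ground-truth dict with the per-epoch target counts.
    """
    config.validate()
    if config.rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    series, truth = simulate_epoch_series(config)
    duration_s = config.raw_duration_s
    total_s = config.n_days * 86400.0
    if duration_s is None:
        duration_s = total_s
    if not 0 < duration_s <= total_s:
        raise ValueError("raw_duration_s must be in (0, n_days*86400]")

    n = int(round(duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    epoch_idx = np.minimum((t / config.epoch_s).astype(int), series.n_epochs - 1)
    target = np.nan_to_num(truth["target"], nan=0.0)[epoch_idx]
    amp = target * np.pi / (2.0 * config.epoch_s)
    x = amp * np.sin(2 * np.pi * config.carrier_hz * t)
    y = np.zeros(n)
    z = np.ones(n)  # static gravity, removed by the bandpass

    keep = np.ones(n, dtype=bool)
    for day, start_h, dur_h in config.nonwear_gaps:
        a, b = (day * 24 + start_h) * 3600.0, (day * 24 + start_h + dur_h) * 3600.0
        keep &= ~((t >= a) & (t < b))

    df = pd.DataFrame({"t_s": t[keep], "x_g": x[keep], "y_g": y[keep], "z_g": z[keep]})
    df.to_csv(path, index=False, float_format="%.6f")
    return {"target_counts": truth["target"], "series": series, "truth": truth}


def simulate_cohort_table(
    n: int = 40,
    seed: int = 0,
    beta_iv_speed: float = 0.4,
    beta_onset_memory: float = -0.3,
    iv_effect_tau: int = 40,
    iv_family_corr: float = 0.8,
) -> pd.DataFrame:
    """Participant-level table with planted rhythm-cognition effects.

    Confounders (age, sex, education, recording length) influence the
    cognitive outcomes; rhythm metrics are drawn independently of the
    confounders. Processing speed loads on the IV value at
    ``iv_effect_tau`` minutes with standardized slope ``beta_iv_speed``;
    delayed memory loads on activity onset (up-mesor) with slope
    ``beta_onset_memory``. IV values share a common factor across timescales
    (correlation ``iv_family_corr``), mimicking the strong inter-timescale
    correlation of real fragmentation metrics.
    """
    if not 0 <= iv_family_corr < 1:
        raise ValueError("iv_family_corr must be in [0, 1)")
    if iv_effect_tau not in IV_TAUS_MIN:
        raise ValueError(f"iv_effect_tau must be one of {IV_TAUS_MIN}")
    rng = np.random.default_rng(seed)
    age = rng.normal(67.2, 8.4, n)
    sex = (rng.random(n) < 0.725).astype(float)
    education = (rng.random(n) < 0.725).astype(float)
    rec_len = np.clip(rng.normal(6.9, 0.9, n), 3.0, 8.0)

    factor = rng.standard_normal(n)
    iv_z = {}
    for tau in IV_TAUS_MIN:
        eps = rng.standard_normal(n)
        iv_z[tau] = np.sqrt(iv_family_corr) * factor + np.sqrt(1 - iv_family_corr) * eps
    onset_z = rng.standard_normal(n)

    def conf_signal():
        return (
            -0.02 * (age - age.mean())
            + 0.1 * (sex - sex.mean())
            + 0.2 * (education - education.mean())
            + 0.05 * (rec_len - rec_len.mean())
        )

    resid_sd_speed = np.sqrt(max(1.0 - beta_iv_speed**2, 0.05))
    resid_sd_mem = np.sqrt(max(1.0 - beta_onset_memory**2, 0.05))
    speed_z = (
        beta_iv_speed * iv_z[iv_effect_tau] + conf_signal() + resid_sd_speed * rng.standard_normal(n)
    )
    memory_z = (
        beta_onset_memory * onset_z + conf_signal() + resid_sd_mem * rng.standard_normal(n)
    )

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "recording_length": rec_len,
            "immediate_memory": 26.7 + 5.2 * rng.standard_normal(n),
            "delayed_memory": 8.7 + 2.8 * memory_z,
            "processing_speed": 10.3 + 2.8 * speed_z,
            "set_shifting": 40.1 + 31.6 * rng.standard_normal(n),
            "pseudo_f": np.exp(rng.normal(5.0, 0.8, n)),
            "interdaily_stability": np.clip(rng.normal(0.6, 0.12, n), 0.05, 0.98),
            "relative_amplitude": np.clip(rng.normal(0.85, 0.08, n), 0.2, 0.999),
            "up_mesor": 7.5 + 1.2 * onset_z,
            "down_mesor": 21.5 + 1.2 * rng.standard_normal(n),
        }
    )
    for tau in IV_TAUS_MIN:
        # plausible positive IV scale, decreasing with timescale
        table[f"iv_{tau}"] = np.exp(np.log(1.0 / np.sqrt(tau)) + 0.3 * iv_z[tau])
    return table
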