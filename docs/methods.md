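# Methods

This note records the models, conventions, and numerical choices behind
`wristrhythm`, and what the synthetic-data tests do and do not establish
about real recordings.

## From raw acceleration to counts

Raw input is a delimited stream `t_s,x_g,y_g,z_g` at a nominal rate between
25 and 200 Hz (50 Hz typical for consumer wrist devices). Duplicate
timestamps are averaged; recordings whose median inter-sample interval
deviates more than 10% from the nominal rate are rejected rather than
silently resampled. Each axis is filtered with a zero-phase 4th-order
Butterworth bandpass, default 0.25–3.0 Hz — the standard wrist
human-movement band; the high-pass edge removes the static gravity
component, so counts are orientation-invariant. The per-sample Euclidean
norm of the three filtered axes is averaged within each 30-s epoch and
scaled by the epoch length to give the count. This definition is
positively homogeneous (scaling accelerations by c scales counts by c),
which the property tests exploit. Epochs observing fewer than 50% of their
expected samples are missing. Filtering runs across sample gaps as if they
were absent; the affected epochs are below the completeness threshold and
discarded anyway, so the approximation never reaches downstream stages.

The filter family, order, and band are configuration, not claims: on-device
count algorithms differ, and no attempt is made to match any vendor's counts
bit for bit.

## Wear screening

Nonwear detection is count-based: every maximal run of at least 90 minutes
in which counts stay at or below 1% of the recording's median positive count
is nonwear, and missing epochs are nonwear by definition (they also extend
adjacent low-count runs). Devices with hardware wear sensing can supply
their own `WearMask` instead.

The main sleep period is the circular 8-hour window minimising the mean of
the person's average 24-h profile (worn epochs only; ties go to the earliest
clock start). Each calendar day's sleep period is the clock window
intersected with that day — a window wrapping midnight contributes its
late-evening and early-morning parts to the *same* day — so every day is
screened self-contained and first/last days need no neighbours. A day is
valid iff its nonwear (24 h minus worn hours, so time outside the recording
counts as nonwear) is at most 4 h **and** no nonwear epoch falls in its
sleep period; a day with at least 22 worn hours earns a star; a recording is
adequate with at least 3 consecutive valid days. Censoring replaces nonwear
epochs and whole invalid days with missing values and never alters a
retained count; no stage anywhere imputes.

"Recording length" is reported both as the integer number of calendar days
containing worn data and as total worn hours / 24; the real-valued version
is the covariate used in the association stage.

## Extended cosine model

The fitted curve is

    y(t) = min_level + amplitude · expit(β (cos(2π(t − φ)/24) − α))

with a fixed 24-h period. `α ∈ (−0.999, 0.999)` sets the fraction of the
cycle spent above mid-range (wide vs narrow active period); `β ∈ (0.1, 50)`
sets transition steepness (large β approaches a square wave). Missing epochs
are excluded from the loss. Fitting is bounded trust-region least squares
with an analytic Jacobian, tolerances 1e-12, and 8 restarts jittering the
initial acrophase ±3 h (seeded); the initial acrophase is the peak of the
1-h-smoothed mean daily profile, and min/amplitude start at the 5th/95th
count percentiles. The winner is the restart with the lowest residual sum of
squares.

Rhythm robustness is the extra-sum-of-squares pseudo-F against the grand
mean with k = 5 parameters:

    pseudo_F = ((RSS_null − RSS_model)/(k − 1)) / (RSS_model/(n − k)).

Activity onset/offset are the curve's crossings of `min + amp/2`, which the
logistic reduces to the closed form `φ ∓ (24/2π)·arccos(α)` (up-mesor is the
ascending crossing). These conventions (dof = n − 5, mean-only null) are
this package's choices; other cosinor implementations need not agree
numerically, though the parameter estimates themselves are
model-identical.

Degenerate inputs: an all-constant series has no rhythm variance and is
rejected; series spanning fewer than 3 days of observed data are rejected
because screening adequacy is a precondition for interpreting the fit.

## Nonparametric metrics

All metrics run at native epoch resolution (2880 bins/day at 30 s); nothing
is subsampled to hourly values.

**IS** uses the observation-weighted form
`IS = [Σ_h n_h (x̄_h − x̄)² / Σ_h n_h] / [Σ_i (x_i − x̄)² / N]`,
where bin means are taken over the days actually observed in that bin and
empty bins drop out. For complete data this reduces to the classical ratio;
it is 1 for exactly repeated days and ≈ 1/n_days for structureless noise.

**IV(τ)**: the numerator is the mean squared successive difference of
non-overlapping τ-minute window means (windows partitioned from the series
start; any window containing a missing epoch is dropped, and only temporally
adjacent usable windows are differenced — a censored gap breaks the chain).
The denominator is the *population* variance (ddof = 0) of the
native-resolution observed series and is identical for every τ, so the
12-member family IV(5)…IV(60) shares one scale. The population-variance
choice makes the alternating-series identity exact (IV = 4 for `a,b,a,b,…`
at native τ, any even length) and matches the classical n/(n − 1) prefactor
convention. For iid noise, E[IV(τ)] ≈ 2·(epoch/τ), so the family decreases
with τ; for a rhythm fragmented by state switching at dwell time d, IV(τ)
instead peaks near τ ≈ d — the timescale-resolved signature that motivates
computing the whole family.

A caveat measured during development: on 7-day iid-noise recordings the
*mean* IV(τ) curve over replicates is strictly decreasing, but individual
replicates are monotone across all 12 timescales only ~25–30% of the time —
at τ = 60 min only ~168 non-overlapping windows exist, and the estimator's
sampling noise (~13% CV) exceeds the expected gap between adjacent
timescales (ratio τ/(τ+5)). Per-recording monotonicity should therefore not
be expected, and tests of the decreasing-in-τ property are stated on
replicate means.

**RA** = (M10 − L5)/(M10 + L5), with M10/L5 the extreme means over circular
10-h/5-h windows of the average daily profile, searched at every native
epoch start with wraparound; ties take the earliest clock start; NaN profile
bins are skipped inside windows. A flat zero profile yields RA = 0 with a
warning.

## Association statistics

Outcomes (not predictors) are residualized on the confounders by OLS with an
intercept; the residuals are regressed on each z-scored predictor after
z-scoring, so the slope is a standardized β equal to the Pearson correlation,
with dof = n − 2, t-based 95% CIs, and two-sided p. Residualizing the
predictor as well is available behind a flag but off by default. Rows with
any missing modeled value are listwise-deleted with a logged count. Group
comparisons use the Welch t statistic with Satterthwaite degrees of freedom
in closed form. Within the declared IV family (12 timescales per outcome),
p values become Benjamini–Hochberg step-up q values (monotonicity enforced
by cumulative minima); q values are not computed outside declared families.

## Simulator

`simulate_epoch_series` draws `counts = state(t) · curve(t) · m(t) + e(t)`,
truncated at zero, where `curve` is the same sigmoid-cosine the fitter
estimates (defaults: min 10, amplitude 100 counts, acrophase 14:00, α = 0.2,
β = 4 — a realistic mid-afternoon peak with ~10.5 h between onset and
offset), `m` is optional lognormal multiplicative noise, and `e` optional
additive Gaussian noise. Fragmentation is a two-state rest/active Markov
chain whose exit hazards are modulated by the normalised curve
(`λ_rest→active = 2c(t)/d_rest`, `λ_active→rest = 2(1 − c(t))/d_active`), so
with equal dwell times the stationary active probability tracks the curve
while mean dwell times set the switching timescale. The chain is sampled
exactly from pre-drawn per-state Bernoulli arrays via a transition-index
walk, so cost scales with the number of transitions. Nonwear gaps become
missing epochs. Raw mode writes a 50 Hz stream whose x-axis carries an
in-band sinusoid with per-epoch amplitude `target · π/(2 · epoch_s)` (making
the computed counts equal the target up to filter edge effects) plus unit
gravity on z. One seeded generator drives each call; equal seeds give
byte-identical output.

`simulate_cohort_table` generates participant-level tables with planted
standardized effects (default: IV at 40 min → processing speed, β = 0.4;
activity onset → delayed memory, β = −0.3; n = 40 with cohort-realistic
confounder distributions) for end-to-end checks of the association scan.

What the simulator does *not* emulate: sleep architecture (stages, discrete
naps), device-specific noise floors and quantisation, postural artefacts,
and day-to-day phase drift. Passing recovery tests on simulated data
demonstrates the estimators are correct for the generating model, not that
any particular device's counts satisfy that model.

## Problem sizes and determinism

Tests and the acceptance script use 3–7 day recordings at 30-s epochs,
10–100 simulation replicates, and raw-mode streams of minutes to a few
hours — sizes chosen so the whole suite runs in about a minute on one core
while keeping Monte-Carlo assertions comfortably away from their
thresholds. Every stochastic component takes an explicit seed; pipeline
reruns with identical configuration are byte-identical.
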