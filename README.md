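# wristrhythm

Rest-activity rhythm analysis for wrist-worn accelerometer data, aimed at
studies that relate 24-hour sleep/wake rhythm disruption to cognitive and
health outcomes in older adults. The package covers the full path from a raw
triaxial stream to cohort-level statistics:

1. **Counts** — bandpass-filter a nominal 50 Hz triaxial recording per axis
   (zero-phase Butterworth, default 0.25–3 Hz), take the per-sample vector
   magnitude, and aggregate into 30-second activity counts.
2. **Screening** — detect nonwear (long near-zero runs plus missing data),
   estimate each person's main sleep period (lowest-mean circular 8-h window
   of the average daily profile), and apply valid-day rules: a day is valid
   with ≤ 4 h of nonwear and no nonwear inside the sleep period; a recording
   is adequate with ≥ 3 consecutive valid days; days with ≥ 22 h of worn data
   earn a "star". Invalid days and nonwear are censored, never imputed.
3. **Extended cosine model** — fit
   `y(t) = min + amp · logistic(β(cos(2π(t − φ)/24) − α))`
   by bounded multi-start least squares, and report rhythm robustness
   (pseudo-F against the mean-only model), activity onset (up-mesor) and
   offset (down-mesor): the clock times where the curve crosses
   `min + amp/2`, available in closed form as `φ ∓ (24/2π)·arccos(α)`.
4. **Nonparametric metrics** — interdaily stability (IS), relative amplitude
   (RA = (M10 − L5)/(M10 + L5)), and a 12-timescale intradaily variability
   family IV(τ), τ = 5…60 min in 5-min steps, computed at native epoch
   resolution with a constant denominator so the family is comparable across
   timescales.
5. **Association statistics** — residualize each cognitive outcome on
   confounders (age, sex, education, recording length), regress the z-scored
   residuals on each z-scored rhythm predictor (standardized β with
   dof = n − 2 and t-based CIs), Welch/Satterthwaite group comparisons, and
   Benjamini–Hochberg q values within the IV test family.
6. **Simulator** — synthetic rest-activity series with a known sigmoid-cosine
   mean curve, Markov rest/active switching at controlled dwell times (the
   fragmentation that IV detects), noise, and insertable nonwear gaps —
   ground truth for every stage.

## Worked example

```python
from wristrhythm import (SimulationConfig, simulate_epoch_series, detect_nonwear,
    estimate_main_sleep_period, screen_recording, fit_extended_cosine,
    compute_nonparametric_metrics)

cfg = SimulationConfig(n_days=7, noise_sd=15.0, dwell_rest_min=45, dwell_active_min=45,
                       nonwear_gaps=[(2, 9.0, 1.0)], seed=42)
series, truth = simulate_epoch_series(cfg)
mask = detect_nonwear(series)
window = estimate_main_sleep_period(series, mask=mask)
result = screen_recording(series, mask, window)
fit = fit_extended_cosine(result.censored, seed=0)
m = compute_nonparametric_metrics(result.censored)
```

prints, via the obvious format strings:

```
sleep window: 22.19-6.19 h
valid days: 7/7, adequate: True
acrophase 14.28 h, up-mesor 9.77 h, down-mesor 18.79 h, pseudo-F 12028
IS 0.737, RA 0.870, IV(5 min) 0.053, IV(60 min) 0.218
```

The simulated rhythm peaks at 14:00 (recovered acrophase 14.28 h) and the
7 days are internally consistent (IS 0.74) with a strong day-night contrast
(RA 0.87). Because the rest/active switching was generated with 45-minute
dwell times, fragmentation is concentrated near that timescale: IV is small
at τ = 5 min and four times larger at τ = 60 min — exactly the
timescale-resolved signature the IV family exists to expose.

The same stages are available from the shell:

```sh
wristrhythm simulate --config sim.yaml --out counts.csv
wristrhythm screen   --counts counts.csv --out report.json --censored censored.csv
wristrhythm cosinor  --counts censored.csv --seed 7 --out fit.json
wristrhythm metrics  --counts censored.csv --iv-taus 5:60:5 --out metrics.json
wristrhythm associate --table cohort.csv --config roles.yaml --out results.csv
wristrhythm pipeline --config pipeline.yaml --out outdir/
wristrhythm actogram --counts censored.csv --double-plot --out actogram.csv
```

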