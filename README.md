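# emadyn

Within-day dynamics of arousal-related symptoms from ecological momentary
assessment (EMA) data, and their relation to insomnia severity.

## The problem

People with insomnia symptoms do not just report *more* daytime anxiety,
stress, sleepiness and low mood — the way those states move across a single
day may itself differ: higher overall levels, wider swings, sharper
moment-to-moment jumps, or stickier states.  `emadyn` implements the full
analysis pipeline for one-day EMA protocols in which each participant

* carries an Insomnia Severity Index total (ISI, 0–28), and
* rates a small set of arousal items (anxious/nervous, stressed, sleepy,
  down) on a 0–8 ordinal scale at ~6 occasions between ~08:00 and midnight.

It is aimed at researchers in sleep medicine, affective science and
ambulatory assessment who want a tested, reproducible implementation of the
standard affect-dynamics statistics plus penalized-spline diurnal modelling
— together with a synthetic-data generator with known ground truth, so every
stage can be validated by parameter recovery.

## What it computes

**Dynamics statistics** per participant × item over the day's series
`x_1 … x_n` (missing values handled by configurable pair policies):

* mean level: `x̄`
* variability: sample SD (n−1 denominator)
* instability: MSSD `= Σ (x_{t+1} − x_t)² / n_pairs`
* inertia: lag-1 autocorrelation
  `r₁ = Σ (x_t − x̄)(x_{t+1} − x̄) / Σ (x_t − x̄)²`

A sample-level outlier rule removes metric values beyond 4·SD of the column
mean.  Each outcome is regressed on ISI by OLS (slope *b*, SE, 95% t-based
CI, p), one row per metric × item.

**Imputation**: missing ratings are filled by k-nearest-neighbour (default
k = 4) with a weighted Gower distance over time-of-day (up-weighted ×4),
assessment index, ISI and the co-rated items, so temporally close
observations dominate.

**Diurnal modelling**: per item, a penalized additive model

`g(E[y_ij]) = β₀ + b_i + f_ISI(ISI_i) + f_time(t_ij) [+ f_int(ISI_i, t_ij)]`

with a ridge-penalized participant intercept `b_i`, P-spline smooths
(cubic B-splines, second-order difference penalties, double-penalty
shrinkage so null predictors drop out), an optional tensor-product
interaction, Gaussian or Poisson-log response, GCV-selected smoothing
parameters and conditional-AIC model comparison.  Predictions are returned
on a 12 × 12 ISI × time-of-day grid.

**Synthetic data**: a generator producing ordinal EMA datasets with
configurable diurnal baselines (harmonics), linear ISI level effects,
ISI-scaled time-window interactions, person random intercepts, AR(1) noise
whose innovation SD grows with ISI (instability), MCAR missingness, and
full ground truth for recovery testing.

## Worked example

```python
import numpy as np
from emadyn import (SimulationConfig, simulate_dataset, apply_qc,
                    compute_profiles, apply_outlier_rule, run_table,
                    missingness_summary, knn_impute, fit_gam, predict_surface)

cfg = SimulationConfig(n_participants=361, seed=1)   # study-scale defaults
records, truth = simulate_dataset(cfg)
clean, report = apply_qc(records)

profiles = compute_profiles(clean)
profiles, rule = apply_outlier_rule(profiles)
isi = clean.drop_duplicates("participant_id").set_index("participant_id")["isi"]
table = run_table(profiles, isi)
print(table[table["item"] == "anxious"])

imputed, _ = knn_impute(clean)
fit = fit_gam(imputed, "anxious", include_interaction=True)
surface = predict_surface(fit, n_grid=12)
```

Output (abridged):

```
retained 361/361 participants
missing ratings: 791/8664 (9.1%)
    metric     b    se  ci_low  ci_high  p_value
mean_level 0.128 0.012   0.105    0.151    0.000
        sd 0.029 0.004   0.021    0.037    0.000
      mssd 0.098 0.016   0.066    0.130    0.000
      acf1 0.003 0.003  -0.003    0.009    0.290
GAM (anxious): edf time=3.2, isi=0.8, interaction=2.7, AIC=6832.6
predicted rating at ISI=21, t=23.8h: 3.88
```

Read: each ISI point raises the day's mean anxiety rating by ≈ 0.13 points
and the MSSD (instability) by ≈ 0.10 squared points — both clearly
significant — while inertia (acf1) shows no ISI association; this matches
the generator's configured effects (level slope 0.118, an ISI-dependent
innovation SD, no inertia effect).  The fitted surface gives the expected
rating for any ISI × time-of-day combination with the person effects
averaged out.

## Command line

Every stage is also a CLI subcommand (a thin wrapper over the library):

```bash
ema-dyn simulate --out data.csv --seed 1
ema-dyn qc --in data.csv --out clean.csv --report qc.json
ema-dyn metrics --in clean.csv --out profiles.csv
ema-dyn regress --profiles profiles.csv --data clean.csv --out table1.csv
ema-dyn impute --in clean.csv --out imputed.csv --k 4 --time-weight 4
ema-dyn fit-diurnal --in imputed.csv --item anxious --out surface.csv
ema-dyn run-all --config pipeline.yaml --out results/ --seed 1
```

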