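# Methods

This note documents the models and procedures `emadyn` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
simulation-based tests do and do not establish.

## Data model

Long-format records, one row per (participant, occasion, item):
`participant_id, isi, assessment_index, time_of_day, item, rating`.
Ratings are ordinal integers 0–8 (or missing); ISI is an integer 0–28 per
participant; time-of-day is continuous clock hours, with responses after
midnight encoded as hours > 24 so time stays monotone within the day and the
diurnal smooth sees no wrap-around discontinuity.

## Synthetic-data generator

The generator emulates a one-day EMA protocol at study scale: 361
participants, six occasions scheduled at 08:30–23:00 (per-person Gaussian
timing jitter, SD 0.5 h, forced increasing, floored at 08:00), four items,
8.8% of cells deleted completely at random.  The latent trajectory is

    y*_ijm = baseline_m(t_ij) + slope_m · ISI_i + inter_m(ISI_i, t_ij)
             + b_i + e_ijm

* **baseline_m** — a constant plus low-order 24-h harmonics per item.  The
  default shapes give anxiety morning + evening peaks, stress an evening
  peak, sleepiness a U across the waking day, and a flat profile for
  feeling down.
* **slope_m** — linear level effect of ISI; defaults 0.118 / 0.140 / 0.115 /
  0.131 rating points per ISI point for anxious / stressed / sleepy / down.
* **inter_m** — Gaussian time windows scaled by standardized ISI
  (`z = (ISI − mean)/SD`), so `interaction_amplitude` is the rating-point
  elevation inside the window per SD of ISI.  The window profile is centered
  over the nominal schedule, making the interaction a pure redistribution of
  symptoms across the day: the implied daily-mean slope stays at `slope_m`.
* **b_i** — person random intercept, SD 1.0, shared across items.
* **e_ijm** — AR(1) across occasions (coefficient 0.3, stationary start)
  with innovation SD `0.8 + 0.032 · ISI_i`.  The ISI term is the
  instability mechanism; 0.032 was sized analytically so the implied
  MSSD-on-ISI slope is ≈ 0.106–0.11 squared points per ISI point at the
  default noise level.

Observed ratings are `clip(round_half_even(y*), 0, 8)`; round-half-even is
an unbiased discretization.

ISI totals are drawn from a truncated normal on [−0.5, 28.5] and rounded.
The parent location/scale are **moment-matched** so the truncated
distribution itself has the configured mean 9.1 / SD 5.2 — direct
parameterisation would inflate the sample mean by ≈ 0.4 points through the
lower truncation.

**What the generator does not emulate**: missingness is MCAR at the cell
level (real refusal patterns are plausibly time- and state-dependent);
residuals are AR(1)-homogeneous in time rather than clock-time dependent;
items share only the random intercept (no item-specific factor structure);
there are no weekday, context or measurement-reactivity effects.  Passing
recovery tests therefore demonstrates correctness of the estimators under
these stated conditions, not robustness to every misspecification real data
can offer.

## Quality control

Participants are excluded if they completed fewer than 3 of 6 occasions
(an occasion counts as completed when ≥ 1 item rating is present — the most
permissive reading consistent with item-level missingness surviving QC), or
if they failed more than one of the three data-quality checks (two
attention, one honesty).  Check scoring is supplied as a per-participant
failure-count table; the rules are idempotent and commute, and a
participant caught by both is attributed to the minimum-assessments rule.

## Dynamics statistics

Per participant × item, on **observed** (non-imputed) ratings in occasion
order: mean; sample SD (n−1 denominator — the default of mainstream
statistical software); MSSD with the number of successive pairs as
denominator; lag-1 autocorrelation normalised by the full-series sum of
squares.  That ACF estimator is biased toward zero at n = 6; it is used as
defined because it is the standard series estimator, and the bias is
identical across participants so ISI associations are not distorted by it.

Missing-data pair policy for MSSD: `skip_gaps` (default) pairs consecutive
*observed* occasions — with only six points, dropping every pair adjacent to
a gap (`adjacent_only`, also available) discards too much information.

Outliers: per (metric, item) column over the retained sample, values with
|z| > 4 (mean/SD computed once, non-iteratively) are set missing and
logged.

Each metric × item column is regressed on ISI (treated as continuous) with
closed-form OLS; inference uses the t distribution with n−2 df.  No
multiple-testing correction is applied across the 16 rows by default
(matching the raw-p reporting convention for this table); a
Benjamini–Hochberg option exists.  The intercept is reported but depends on
the uncentered ISI origin.

## kNN imputation

Distance between two observation moments is a weighted Gower distance:
every numeric feature range-scaled to [0, 1], absolute differences averaged
with weights, features missing on either side dropped pairwise.  The
feature set is time-of-day (weight 4 — the temporal up-weighting is the
point of the method; the exact weight is this package's choice),
assessment index, ISI, and the same-moment ratings of the other items
(weight 1 each).  Donors are complete observations of the same item across
all participants (within-person pools are too small for k = 4 with six
occasions).  The imputed value is the inverse-distance-weighted mean
(ε = 1e-9 guards zero distances) rounded back to the 0–8 grid; ties in
donor distance break by row order, so the procedure is deterministic.

## Penalized-spline diurnal model

One penalized regression per item on complete (imputed) data:

* **Random intercepts** — participant indicator columns with one shared
  ridge penalty.
* **Marginal smooths** of ISI and time — P-splines in the Eilers–Marx
  convention: cubic B-splines on *uniform* knots extended three spacings
  beyond the data range (10 basis columns per margin by default),
  second-order difference penalties, sum-to-zero column centering.  Uniform
  knots are essential: they make the difference penalty's null space
  coincide exactly with the linear functions of the covariate, so infinite
  smoothing collapses a smooth to its linear part (an invariant the tests
  check to 1e-5).
* **Double-penalty shrinkage** — each smooth carries a second smoothing
  parameter on the projector onto its penalty null space, so a predictor
  with no signal can shrink to zero entirely.
* **Tensor-product interaction** — row-wise Kronecker product of the
  centered margins, penalised by `S_isi ⊗ I` and `I ⊗ S_time` with separate
  lambdas, plus a third shrinkage penalty on their joint null space.
  Without that third term the bilinear ISI × time direction is unpenalizable
  and acts as a permanently free parameter, which wins the AIC comparison
  about half the time even when no interaction was generated.
* **Families** — Gaussian by penalized normal equations; Poisson log-link
  (ratings as counts) by penalized IRLS (deviance tolerance 1e-8, max 200
  iterations).

Numerical safeguards: every penalized block's *functional* null space
(coefficient directions with zero data energy, e.g. the all-ones vector of
a centered margin) is pinned by a fixed unit penalty — these directions
cannot affect fitted values, so the pin is bias-free while keeping the
normal equations positive definite at any lambda; a small absolute floor
(1e-8) and an escalating-ridge Cholesky fallback cover residual
degeneracies.

**Smoothing-parameter selection** is deviance GCV with Wood's γ = 1.4
inflation of the effective degrees of freedom (plain GCV left edge regions
visibly undersmoothed while its profile was nearly flat), minimised by
cyclic coordinate descent over log-spaced grids (three coarse sweeps ×10
steps, one refinement sweep ×10^0.25 steps, bounds 1e-6–1e7).  Near-flat
profiles are resolved toward the smoother fit: the largest lambda within
0.1% of the optimum is taken, in the spirit of the one-standard-error rule.
This selection is a deliberate, documented substitute for restricted-
likelihood methods: it is simpler, fully deterministic, and adequate for
the recovery behaviour the tests verify, but it is a known deviation from
fast-REML smoothing and will not match REML lambda values.

**Model comparison** uses conditional AIC, `−2·loglik + 2·edf` (Gaussian
adds one for the scale parameter), with edf the trace of the influence
matrix.  AIC differences below 1e-3 are numerical noise of the deviance
accumulation and are treated as exact ties, resolved toward the
lower-index (simpler) model.  Cross-family Gaussian-vs-Poisson comparisons
are supported (`family="auto"`) but approximate, since the two likelihoods
live on different dominating measures for the same discrete ratings.

**Prediction** sets the random-intercept block to zero (population level)
and evaluates the smooths on a 12 × 12 grid spanning, by default, the inner
98% (1st–99th percentile) of each training covariate: the absolute range is
typically set by single stragglers (one late responder, one extreme ISI
score) where any surface is pure extrapolation.  Any explicit grid is
accepted; points beyond the training range produce an extrapolation warning.
Standard errors come from the penalized coefficient covariance on the
linear-predictor scale.

## Simulation studies in the test suite

Problem sizes were chosen so each study isolates one question at study
scale while the whole suite stays a few minutes long:

* *Metric oracles*: 1000 random length-6 series against independent
  brute-force implementations (1e-12), plus frozen hand-computed cases.
* *von Neumann identity*: MSSD/(2·var) ≈ 1 − r₁ on AR(1) series of length
  10,000 (tolerance 0.05).
* *Regression calibration*: 500 replicates at n = 361 with level slope
  0.118 (CI coverage 93–97%), 2000 null replicates (type-I 0.05 ± 0.02),
  slope bias < 0.005.  The interaction amplitude is zero in these runs so
  the implied mean-level slope is exactly the configured truth.
* *Instability detection*: 200 replicates with innovation-SD slope 0.032 and
  a flat diurnal baseline.  The flat baseline isolates the mechanism: with
  a time-varying mean, the trend-to-noise ratio falls as ISI rises, which
  deflates the short-series ACF estimate at high ISI and produces a small
  spurious ACF~ISI slope (≈ −0.001) — a caveat that applies to real
  analyses of this design as well.
* *GAM recovery*: diurnal sine + ISI-scaled evening bump, innovation SD
  0.5, no person intercepts or serial correlation, n = 361 × 6; surface
  RMSE < 0.15 rating points on the default grid.  With the full default
  generator (person intercepts SD 1.0) RMSE is ≈ 0.11–0.17.
* *AIC selection*: 100 seeds per arm at n = 120 with iid innovations.
  Serial correlation is outside this model class (no autocorrelated
  residual structures are fitted) and makes conditional AIC
  anti-conservative regardless of the interaction, so the iid condition is
  what a selection-power study should use.
* *Imputation*: 20 MCAR mask/reconstruct replicates at study scale;
  time-weighted kNN must beat per-item mean imputation.

## Known limitations

* Smoothing-parameter selection is GCV-based, not REML; lambdas and edf are
  not comparable to REML-based software even when fits look identical.
* The ACF estimator at six observations is strongly biased toward zero;
  only its *association* with ISI is interpretable, not its level.
* Conditional AIC with GCV-selected lambdas remains somewhat liberal; the
  null-interaction arm of the selection study prefers the interaction model
  in a minority (but not a negligible fraction) of seeds.
* No autocorrelated residual structures, no smooth-specific p-values, no
  multi-day designs, no MNAR missingness mechanisms.
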