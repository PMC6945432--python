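# Methods

This note documents the modelling and numerical choices behind `redsnn`: what
is simulated, how the network is trained, how probabilities are read out, and
what the synthetic experiments do and do not demonstrate.

## Synthetic cohort model

Cohorts are drawn from a Weibull proportional-hazards law.  Each covariate
contributes a design value (its level index; continuous age/size contribute
their binned level) scaled by its standard deviation, so effect sizes read as
log-hazard ratios per SD.  The latent event time is

    T = scale · (−ln U / exp(xβ − a))^(1/shape),   U ~ Uniform(0,1)

with shape 1.3 and scale 90 months.  The anchor `a` (`baseline_log_offset`,
default 10.93) is a fixed constant equal to the mean risk load of the default
schema; it makes `scale` the time scale of an average-risk patient while
keeping the design columns non-negative.  Non-negative columns matter for one
invariant: raising a positive effect size then raises every patient's hazard,
so the population event rate before any horizon cannot decrease.  (With
mean-centered columns that monotonicity is genuinely false — increasing a
coefficient adds log-hazard dispersion, and by Jensen's inequality more
dispersion can *lower* the average event probability.)

Observed time is min(latent time, exponential censoring time, administrative
horizon of 120 months); `event = 1` iff the latent time is the minimum.  The
censoring rate default (0.0058/month) was calibrated once by simulation so
that the default cohort is ≈49 % censored, matching the registry structure
being emulated.  Missingness is injected completely at random per column
(defaults: grade 19 %, tumor size 36 %).

The default schema has 14 covariates whose one-hot/ordinal expansion is
exactly 26 features (10 categorical → 22 channels; age group, grade, size
group, tumor count → 4 ordinal channels).  Level frequencies loosely mirror a
spino-pelvic chondrosarcoma registry table; effect sizes encode a-priori
clinical expectation (stage 1.3, grade 1.2, age 1.0 and no-surgery 1.0 per SD
are the informative signals; the rest are ≤0.5).  What the generator does
*not* emulate: joint covariate dependence, informative censoring, competing
risks, or time-varying covariates.  Tests passing on these cohorts therefore
demonstrate correctness of the machinery and recoverability of a known risk
ordering — not clinical performance on real registry data.

## Preprocessing

Age bins at 30-year intervals (0–29, 30–59, >59); tumor size binarizes at
80 mm; grade and tumor count stay ordinal; everything else one-hots (an
explicit Unknown level absorbs missing categorical entries where declared).
The 80/20 split and the 5-fold cross-validation folds come from seeded
shuffles without outcome stratification.  k-NN imputation (k = 5, NaN-aware
Euclidean distance rescaled by the observed fraction) and z-scoring are
fitted on training rows only; the leakage guard is tested by permuting apply
rows and checking the fitted statistics are untouched.

## Window targets and loss

Windows are left-open, right-closed intervals ((i−1)m, i·m], i = 1..W with
W = floor(horizon/m); a death exactly on a boundary belongs to the earlier
window.  With the defaults m = 2 and horizon = 62 this yields 31 windows.
A patient dead by the boundary contributes target (α, death time) from that
window on; a patient observed past the boundary contributes (0, boundary);
a patient censored by the boundary leaves the loss permanently, with the
censoring time frozen for inspection.  At-risk targets (0, t) are admissible
in the cosine because t > 0 keeps the norm positive; estimates are guarded by
an ε = 1e-8 norm floor, which makes the analytic gradient a subgradient at
degenerate points.  The loss is computed jointly on the 2-D (risk, time)
vector — the event and time targets are learned simultaneously, not as two
separate losses.

## Network and training

Default stack (8 layers): input 28 = 26 features + 2 latent survival
channels, then 24 (FC/ReLU) → 20 (LSTM) → 16 (LSTM) → 12 → 8 → 4 (FC/ReLU)
→ 2 linear output nodes (risk, time); no softmax, because the outputs live on
different scales.  Optional dropout (0.3/0.5/0.7) sits between the first FC
layer and the LSTM stack, and a "bignode" multiplier widens all hidden
layers.  The two latent channels carry the previous window's estimate,
rescaled to (ê/α, t̂/horizon) so they enter on the same scale as the
standardized features; they are zero at the first window.

Training walks the windows chronologically within each epoch: per batch and
per window, one forward step, the masked cosine loss, one RMSProp update
(lr 1e-3, ρ 0.9, batch 64).  Backpropagation is truncated at one window — the
incoming LSTM state and the latent feedback are treated as constants — which
matches the serial re-training reading of the procedure and keeps every
gradient verifiable against finite differences (tested to 1e-4 relative).
Weights initialize Glorot-uniform from a seeded generator, LSTM forget-gate
biases at 1, and the output bias at (1, 30) so the first estimates start in
the positive quadrant at a plausible follow-up scale.  Everything is float64
NumPy; a 1 400-patient, 31-window training takes a few seconds on one core.

Epochs default to 2.  In cross-validated comparisons on synthetic cohorts the
base unit begins to overfit past ~4 epochs (training c-index keeps rising
while held-out c-index falls), and the dropout-0.3 variant generalized best
among the architecture variants, so dropout 0.3 is the shipped default.

## Probability readout and calibration

The cosine loss is scale-invariant in the estimate, so the raw risk output ê
carries no probability scale; only the direction of (ê, t̂) is identified.
The direct readout S = 1 − clamp(ê/α, 0, 1) is provided
(`survival_probability`) but is *not* calibrated.  The pipeline instead uses
the scale-free per-window risk score s = ê/|Ŷ| (the sine of the estimate's
angle off the time axis) and fits, per window, a monotone link from score to
P(survive past the boundary):

1. rank-normalize the score against the training distribution (probit of the
   empirical CDF), which removes the score's arbitrary, often bimodal scale;
2. fit a binomial GLM with complementary-log-log link, cubic in the
   normalized score, weighting patients by inverse probability of censoring
   (alive past the boundary: weight 1/G(b); dead by it: 1/G(T−); censored
   earlier: 0; G = Kaplan-Meier of the censoring distribution; weights capped
   at 20).  Under proportional hazards with a roughly Gaussian linear
   predictor, log(−log S) is approximately polynomial in the normal rank, so
   this family is both smooth and well specified for the synthetic truth;
3. project the fitted curve onto the decreasing cone (pool-adjacent-violators
   on a dense grid, weighted by the rank-normal density so sparse tails
   cannot drag the dense center).

Simpler alternatives were rejected after comparison on held-out cohorts:
patient-level isotonic regression does not transfer in sparse score regions,
and a 2-parameter cloglog link is too rigid in the tails.

A consequence of honest calibration: with held-out discrimination around
c ≈ 0.80, no patient's calibrated 62-month survival exceeds ~0.95, so the
best prognostic band (> 0.96) of the 5-group stratification is typically
empty on synthetic cohorts; evaluation reports and tests operate on the
realized non-empty subgroups.

## Evaluation protocol

* c-index: Harrell's c over comparable pairs, on the final-window risk score
  (last-follow-up information); risk ties count ½.
* Time-dependent AUC per window: cases = dead by the boundary, controls =
  known alive beyond it, censored-out excluded; mid-rank tie handling;
  degenerate windows are dropped from the mean/SD.
* Calibration: patients ranked by predicted survival at the 60-month horizon
  (five years), cut into 7 equally numerous bins (remainders to the
  lowest-rank bins); each bin's mean prediction is compared with the
  Kaplan-Meier actual at the horizon.
* Stratification: predicted 62-month survival cut at {0.96, 0.78, 0.53,
  0.32} into five half-open bands ([0.96,1], [0.78,0.96), [0.53,0.78),
  [0.32,0.53), [0,0.32)) — the published percent bands leave gaps, so the
  half-open partition makes group assignment exhaustive.  Neighboring
  subgroups are compared with two-group log-rank tests; p-values are raw and
  two-sided, with no multiplicity correction.
* Mann-Whitney comparisons use exact enumeration for combined n ≤ 12 without
  ties, otherwise the tie-corrected normal approximation.

Hyperparameter tuning scores each grid point by the median validation
c-index over the 5 folds (imputation and scaling re-fitted inside each fold)
and breaks ties by grid order; the selected setting is then retrained on the
whole training set.

## Problem sizes and experiment design

The shipped experiments use cohorts of 1 000 patients (discrimination:
held-out c-index versus the true linear predictor, null-signal and
label-shuffle controls) and 1 400 patients (calibration and stratification,
measured over the full cohort of that run: a 7-bin Kaplan-Meier comparison
needs ≈200 patients per bin before its sampling error is small relative to a
0.10 margin).  Stochastic checks run three fixed seeds and require a
majority to pass.  These sizes mirror the registry cohort the model was
designed around (~1 100 patients) and complete in seconds each.

## Known limitations

* Truncated (one-window) backpropagation means long-range credit assignment
  through the LSTM state is learned only implicitly; the model underfits the
  true risk ordering by roughly 0.05 c-index relative to a Cox model on the
  same features.
* The calibration link is fitted on training predictions; a mildly
  overfitted network shifts the score distribution on new data and leaves
  calibration errors of a few percentage points.
* The survival-probability mapping is a package-level definition; the
  training objective itself never sees probabilities.
* The generator's missingness is MCAR and its covariates independent, which
  flatters k-NN imputation relative to real registry data.
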