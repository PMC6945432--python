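# redsnn

A recurrent survival neural network with a cosine **risk-estimate-distance
(RED)** loss, for right-censored tabular cohorts — together with the synthetic
registry-like cohort generator, preprocessing, and evaluation protocol needed
to exercise it end to end.

## Who this is for

Researchers in survival analysis / clinical prognostication who want a
discrete-time-window deep survival model that learns the event indicator and
the follow-up time *jointly*, plus a fully reproducible synthetic test bed.
Population registry extracts (e.g. cancer registry data) require formal access
requests and cannot be bundled; the package instead generates seeded cohorts
with the same structure — ~14 mixed categorical/ordinal covariates, per-column
missingness, ≈50 % censoring, follow-up beyond five years — from a Weibull
proportional-hazards law with a known true risk ordering.

## The model

A patient's survival state in time window *i* is a 2-D vector

```
Y_i = (α·E_i, t_i)
```

where `E_i ∈ {0,1}` is the cumulative death indicator by the window boundary,
`t_i` the last observed time (months), and `α > 0` a hyperparameter weighting
death against follow-up time.  The **risk estimate distance** between two
survival states is their cosine distance

```
RED(A, B) = 1 − (A·B) / (|A||B|)
```

which is 0 for parallel states, 1 for orthogonal ones, and — for a death
compared with same-time survival — strictly larger the earlier the death:
`RED((α,t),(0,t)) = 1 − t/√(α²+t²)`.

The network (8 layers: a 28-node input = 26 encoded features + 2 latent
survival channels fed back from the previous window, one fully connected ReLU
layer, two LSTM layers, three more ReLU layers of decreasing width, and a
2-node linear output for risk and time) is trained window by window in
chronological order, minimizing the masked cosine-proximity loss

```
L(θ) = mean over at-risk/dead elements of 1 − cos(Y, Ŷ)
```

by backpropagation with RMSProp; patients censored out of a window contribute
nothing from that window on.  Defaults follow the protocol the model was
designed with: window length m = 2 months, horizon 62 months (31 windows),
α = 10, 2 epochs.  Because the cosine loss constrains only the *direction* of
the estimate, survival probabilities are read out through a monotone,
censoring-aware calibration link fitted on the training set (see
`docs/methods.md`).

Evaluation follows the standard protocol: Harrell's c-index on last-follow-up
risk, time-dependent ROC/AUC per window, 7-bin calibration against
Kaplan-Meier actuals at five years, and stratification of predicted 62-month
survival into five prognostic subgroups compared with log-rank tests.

## Worked example

```python
import dataclasses
from redsnn import (RunConfig, default_cohort_spec, generate_cohort,
                    train_pipeline, evaluate_pipeline)

cfg = RunConfig(cohort=default_cohort_spec(n_patients=1000), seed=1)
table = generate_cohort(dataclasses.replace(cfg.cohort, seed=1))
bundle = train_pipeline(cfg, table=table)      # split, impute, scale, train
report = evaluate_pipeline(bundle, table=table)  # held-out evaluation

print(f"held-out c-index: {report.c_index:.3f}")
print(f"mean time-dependent AUC over {len(report.aucs)} windows: "
      f"{report.auc_mean:.3f} (SD {report.auc_sd:.3f})")
```

prints

```
held-out c-index: 0.796
mean time-dependent AUC over 31 windows: 0.883 (SD 0.012)
```

i.e. on a strong-signal synthetic cohort of 1000 patients the trained network
ranks held-out patients' survival with c = 0.80 (the true linear predictor —
the best possible score — reaches 0.88 on the same split), and discriminates
dead from surviving patients within each 2-month window with a mean AUC of
0.88.  The `report` object also carries the calibration bins, the subgroup
Kaplan-Meier curves and the neighboring-pair log-rank tests, and serializes
losslessly to JSON.

The same pipeline is scriptable from the shell:

```
redsnn simulate --seed 1 --out cohort.csv
redsnn train    --seed 1 --cohort cohort.csv --out artifacts/
redsnn evaluate --seed 1 --cohort cohort.csv --artifacts artifacts/ --out report/
```

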