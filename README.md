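# ec50ml

Quality-aware EC50 estimation and QSAR modelling from raw dose–response data.

## The problem

Early-stage screening produces dose–response experiments: for each molecule,
percent-effect responses at a series of concentrations. Standard practice
compresses each molecule's measurements into a single potency metric — the
EC50 (or IC50 for inhibition assays), the concentration giving a 50% effect —
by fitting the 2-parameter Hill equation

    response(X) = 100 / (1 + 10^((LogEC50 − X) · HillSlope)),   X = log10(concentration)

and then trains structure–activity (QSAR) models to predict LogEC50 from
molecular fingerprints. The compression discards how *well* the curve fitted:
a molecule measured four times with heavy noise gets the same kind of number
as one measured a hundred times cleanly. `ec50ml` keeps that information. For
every molecule it produces, alongside the LogEC50 target:

* **regression mode** — a fit-quality metric *z*, the mean squared residual of
  the least-squares Hill fit, or
* **Bayesian mode** — the variance of a posterior sample of LogEC50, computed
  on a 100×10 grid over (LogEC50, HillSlope) under a pooled-variance Gaussian
  noise model,

and feeds it to learners that can exploit it. The quality metric enters
through one transform, the selection probability

    p_i ∝ exp(−α z_i),

where α ≥ 0 sets how strongly poorly-fitted molecules are discounted (α = 0
recovers the standard, quality-blind model). Seven model families are built
on top: a plain random forest (RF), a forest whose per-tree bootstrap draws
points with probabilities p_i (PB-RF), a forest with weighted
variance-reduction splits and weighted leaf means (W-RF), an output-smearing
forest (OS-RF, per-tree Gaussian target noise of variance β replaces random
feature selection), a variable-output-smearing forest (VOS-RF, worse-fitted
points are smeared more, mean variance β), and epsilon-SVR with RBF kernel,
plain (SVR) and with per-sample penalties n·p_i (WSVR).

Models are evaluated the way the targets deserve: never by reproducing
possibly unreliable held-out EC50s, but by predicting the held-out *raw*
measurements — the predicted LogEC50 plus a unit Hill slope determines a
predicted response at every tested concentration, and models are scored by
the RMSE over all held-out (dose, response) pairs, with bootstrap SDs and
one-sided Wilcoxon signed-rank comparisons at the 0.1% level.

## Worked example

```python
import numpy as np
from ec50ml import (
    ModelSpec, basf_like, build_quality_table, evaluate_on_dose_response,
    regression_targets, split_dataset, train_model, wilcoxon_compare,
)

data = basf_like(400, seed=7)                      # heteroscedastic synthetic assay
train, test = split_dataset(data.sets, 0.5, seed=7)

targets = regression_targets(train)                # Hill fits -> LogEC50 + quality z
table = build_quality_table(targets, data.features)

blind = train_model(table, ModelSpec("RF", {"max_features": 0.33,
                                            "min_samples_split": 0.01}, seed=7))
aware = train_model(table, ModelSpec("W_RF", {"max_features": 0.33,
                                              "min_samples_split": 0.01,
                                              "alpha": 1.0}, seed=7))

lookup = data.feature_lookup()
rep_blind = evaluate_on_dose_response(blind, test, lookup, model_label="RF")
rep_aware = evaluate_on_dose_response(aware, test, lookup, model_label="W_RF")
print(rep_blind.summary())
print(rep_aware.summary())
print(wilcoxon_compare(rep_aware, rep_blind))
```

Output:

```
Dose-response evaluation: RF
  measurements : 10497
  molecules    : 200
  RMSE         : 23.04
  bootstrap SD : 0.26
Dose-response evaluation: W_RF
  measurements : 10497
  molecules    : 200
  RMSE         : 23.06
  bootstrap SD : 0.26
Wilcoxon signed-rank (one-sided, 10497 informative pairs, approx): p = 0.8063;
A is not significantly better than B at the 0.1% level (trend: b_better)
```

The RMSE is in response-percent units over all held-out measurements; the
bootstrap SD resamples individual (observed, predicted) pairs; the Wilcoxon
line compares the two models' per-measurement squared errors. At this sample
size (200 training molecules) the two forests are statistically
indistinguishable — quality information only pays off when the quality
spread is large relative to what the model can learn; see `docs/methods.md`.

## Command line

The same pipeline as five commands, each writing its resolved configuration
for provenance:

```bash
ec50ml simulate --preset basf_like --n 400 --seed 7 --train-fraction 0.5 --out data/
ec50ml analyze  --doses data/train_doses.csv --features data/features.csv \
                --mode regression --out analysis/
ec50ml train    --table analysis/table.csv --family W_RF --seed 7 --out model/
ec50ml evaluate --model model/model.joblib --doses data/test_doses.csv \
                --features data/features.csv --out eval/
ec50ml compare  --report-a eval/pairs.csv --report-b eval_rf/pairs.csv --out cmp.json
```

Dose–response files are long-format CSV (`molecule_id, concentration,
response`, one measurement per row, one concentration unit per file);
features are a wide CSV keyed by `molecule_id` with 0/1 columns.

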