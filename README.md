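# caredemand

Predicting which older adults will need formal care services — nursing,
rehabilitation, home health aid, medical monitoring — from routinely
collected health indicators is a binary classification problem with
high-dimensional, nonlinear tabular inputs.  `caredemand` implements a
hybrid prediction method for this problem and, because the survey
populations such models are built on cannot be redistributed, ships a
fully documented synthetic cohort generator so every stage is testable
end to end.

## Method

Each individual's record (chronic disease count, ADL and IADL scores,
mental-health score, total expenditure, hospitalization frequency,
medication count, plus any extra columns) is min-max normalized,
arranged in a fixed order and tiled into a length-*L* "health signal"
*x(t)*.  A *J*-level discrete wavelet transform (orthonormal Haar by
default) splits the signal into an approximation band cA_J and detail
bands cD_1..cD_J; from every band the package extracts time-domain
statistics (mean, variance, standard deviation, skewness, kurtosis),
the band energy E_j = Σ|c_j[n]|², a sample-entropy complexity measure
SampEn(a, b) = −ln(H_a/G_a), and globally the wavelet energy entropy
H = −Σ p_j ln p_j with p_j = E_j/E_total.

Candidate features (raw variables ∪ derived features) are scored by the
information gain ratio IGR(F) = [H(R) − H(R|F)]/H(F) and mutual
information MI(F;R), and retained under the adaptive selection
threshold

    keep F  ⇔  IGR(F) > α·IGR_max  and  MI(F) > β·MI_max ,

default α = β = 0.5.  Two classifiers are trained on the retained
features:

* a bagged CART ensemble whose trees vote with out-of-bag-accuracy
  weights w_t = A_t / Σ A_t, giving P_RF(y=c|x) = Σ_t w_t·1[h_t(x)=c],
  with OOB error and permutation feature importance;
* a logistic regression P_LR(y=1|x) = σ(β₀ + Σ β_u x_u) fit by
  full-batch gradient descent on cross-entropy (learning rate 0.01,
  500 iterations, zero initialization).

Predictions are fused convexly: P_final = g·P_RF + (1−g)·P_LR with
g ∈ [0,1] (default 0.5, or tuned on validation data by AUC grid
search).  Evaluation includes accuracy/precision/recall/F1, ROC/AUC,
stratified 10-fold cross-validation with the entire pipeline refit per
fold, and percentile-bootstrap confidence intervals.

## Worked example

```python
from caredemand import (PipelineConfig, evaluate, fit_hybrid,
                        generate_cohort, standard_cohort_config)
from caredemand.hybrid_eval import predict_components

train = generate_cohort(standard_cohort_config(2000, seed=7))
test = generate_cohort(standard_cohort_config(2000, seed=1007))

model = fit_hybrid(train, PipelineConfig(seed=7))
print("selected features:", ", ".join(model.selected_names))

p_rf, p_lr = predict_components(model, test)
fused = 0.5 * p_rf + 0.5 * p_lr
report = evaluate(fused, test["label"].to_numpy())
print(f"fused AUC {report.auc:.3f}  accuracy {report.accuracy:.3f}  "
      f"recall {report.recall:.3f}  F1 {report.f1:.3f}")
```

prints

```
selected features: chronic_disease_count, adl_score, medication_count, cD1_mean, cD1_energy
fused AUC 0.912  accuracy 0.840  recall 0.751  F1 0.766
```

The selection recovered all three planted demand drivers (and two
derived wavelet features), dropped every pure-noise column, and the
fused model discriminates test-set care demand with AUC 0.91 — above
both components alone (forest 0.91, logistic 0.88 on this draw).

The same pipeline is available from the shell:

```
caredemand simulate --n 2000 --seed 7 --standard --out cohort.csv
caredemand train    --data cohort.csv --seed 7 --out model.json
caredemand evaluate --model model.json --data cohort.csv
caredemand cv       --data cohort.csv --seed 7
caredemand importance --data cohort.csv --seed 7 --out importance.csv
```

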