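# parkisense

Wearable-sensor mobility analysis for a hard clinical discrimination:
telling Parkinson's disease (PD) apart from the other parkinsonian
syndromes (MSA, PSP, DLB, CBS, essential tremor with parkinsonian
features, drug-induced and unspecified parkinsonism) that mimic it.
These conditions share tremor, bradykinesia and rigidity; clinics see
roughly fourteen PD patients for every non-PD parkinsonism patient; and
a single lower-back IMU recorded during brief mobility tasks yields
tens of thousands of candidate features for a few hundred participants.
`parkisense` is the full analysis chain for that setting, aimed at
movement-disorder researchers working with digital gait biomarkers and
at methodologists studying severely imbalanced high-dimensional
classification.

The pipeline:

1. **Synthetic cohorts** — six-channel 100 Hz recordings (triaxial
   accelerometer in g, gyroscope in deg/s) for a five-task clinic
   protocol (32-foot walk, quiet stance with eyes open/closed, two
   Timed Up and Go trials, two cognitive-TUG trials), built from
   kinematic templates with known ground-truth segment boundaries and
   tunable minority-class effects (defaults: 260 PD : 18 non-PD).
2. **Signal conditioning** — zero-lag (forward-backward) 4th-order
   20 Hz Butterworth low-pass; CSV/JSON recording round-trip.
3. **Segmentation** — TUG decomposition into sit_to_stand, walk, turn,
   walk, turn, stand_to_sit via trapezoidal integration of angular
   velocity with hysteresis thresholds; stationary-period removal.
4. **Features** — per segment x channel: 42 time-domain + 22
   frequency-domain statistics and the top-10 DFT and Lomb-Scargle
   power amplitudes; 3 cross-channel features per channel pair; trial
   mean/difference derivations for two-trial tasks; constant/non-finite
   column elimination and median imputation fit on training rows only.
5. **MIEE classifier** — mutual-information feature selection for
   EasyEnsemble: five balanced undersampled subsets, per-subset top-30
   nearest-neighbor MI selection, a 1000-tree random forest per subset,
   averaged probabilities. `MIEE(X, y, config).fit()` returns an
   `MIEEResults` with predictions and a `summary()`.
6. **Evaluation** — stratified 3-fold x 5-repeat cross-validation with
   per-participant majority voting; balanced accuracy, sensitivity,
   specificity, F1, AUC-ROC with balanced-bootstrap BCa confidence
   intervals; grouped permutation importance of the five tasks;
   selection tallies; misclassification profiling (t / chi-squared);
   RF-proximity subtype similarity; held-out "challenging case" scoring
   with within-class percentiles.
7. **Baselines** — alternative selectors (unsupervised-RF ranking with
   a max-balanced-accuracy scan, plain MI top-30, decision-tree F1
   ranking, supervised-RF min-AIC scan, random undersampling) and
   NCL + SMOTE resampling in three placements, all under the identical
   CV harness.

The headline metric everywhere is **balanced accuracy** — the mean of
PD recall (sensitivity) and non-PD recall (specificity) — because raw
accuracy is meaningless at a 14:1 imbalance.

## Worked example

A small cohort (18 PD : 6 non-PD) with a subtle minority-class effect
(8% slower postural transitions, 5% slower turns, 10% more sway
power), TUG features only:

```bash
parkisense run --config example.yaml --task-subset tug
```

with `example.yaml`:

```yaml
simulation:
  n_majority: 18
  n_minority: 6
  seed: 11
  effect: {transition_duration: 1.08, turn_velocity: 0.95, sway_power: 1.1}
miee: {n_trees: 200, seed: 11}
cv: {n_repeats: 5, seed: 11}
```

prints:

```
Classification report (PD positive)
  confusion: TP=15 FN=3 FP=1 TN=5
  balanced_accuracy 0.8333
  sensitivity       0.8333
  specificity       0.8333
  f1                0.8824
  auc_roc           0.9259
```

Reading: of 18 PD participants, 15 were voted PD across the five CV
repeats (sensitivity 0.83); of 6 non-PD participants, 5 were voted
non-PD (specificity 0.83); balanced accuracy is their mean. The AUC of
0.93 says the averaged ensemble probabilities rank a random non-PD
participant above a random PD participant 93% of the time. Identical
configs reproduce identical reports — every stage is seeded.

The same objects are available as a library:

```python
from parkisense import (SimulationConfig, simulate_cohort, cohort_labels,
                        assemble_feature_table, cross_validate, evaluate_cv)

cohort = simulate_cohort(SimulationConfig(n_majority=18, n_minority=6, seed=11))
table = assemble_feature_table(cohort)
cv = cross_validate(table, cohort_labels(cohort))
print(evaluate_cv(cv, table.metadata).summary())
```

Other subcommands: `simulate` (write recordings + manifest),
`featurize`, `importance` (grouped task importance), `baselines`.

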