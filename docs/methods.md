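# Methods

`parkisense` implements a wearable-sensor analysis pipeline for a
clinically motivated binary classification problem: distinguishing
Parkinson's disease (PD) from other forms of parkinsonism (multiple
system atrophy, progressive supranuclear palsy, dementia with Lewy
bodies, corticobasal syndrome, essential tremor with parkinsonian
features, drug-induced and unspecified parkinsonism) using a single
six-channel inertial sensor worn on the lower back during brief clinic
mobility tasks. The central statistical difficulty is severe class
imbalance — parkinsonism clinics see roughly one non-PD patient for
every fourteen PD patients — combined with a very high-dimensional
feature space (tens of thousands of sensor-derived features against a
few hundred participants).

## Data model and signal conditioning

A recording is six synchronized channels at 100 Hz: triaxial
acceleration (vertical, mediolateral, anteroposterior; units g) and
triaxial angular velocity (same axes; units degrees/s), with half-open
0-based task markers. Axis naming follows the channel contract used
throughout the package: postural-transition (trunk pitch) pulses are
carried on the anteroposterior gyroscope channel; turns on the vertical
gyroscope channel. Mounting polarity is not assumed: segmentation uses
pulse order, not rotation direction.

All channels pass through a low-pass, 20 Hz, zero-lag, 4th-order
Butterworth filter before segmentation and feature extraction. Zero lag
is realized as forward-backward application (`filtfilt`), so the
effective magnitude response is the squared one-pass response with zero
phase shift. Edge transients are suppressed with reflective padding of
length 3 x order. Note one deliberate numerical choice: the filter is
the standard digital (bilinear-transform) design, whose stopband
attenuation exceeds the analog prototype formula `1/(1+(f/fc)^(2n))`
(the digital filter has a zero at Nyquist). Passband behavior matches
the analytic curve to well under 1%; stopband gains are smaller than the
analytic values. The test suite checks gains against the analytic curve
on the absolute scale.

## Synthetic cohorts

Real recordings from a comparable clinical protocol are not
redistributable, so the package ships a generator whose defaults encode
the emulated study design: 260 majority-class (PD) and 18
minority-class (non-PD) participants, each performing a 32-foot walk,
20 s of quiet stance with eyes open and with eyes closed, and two trials
each of the Timed Up and Go (TUG) and cognitive TUG.

Recordings are built from piecewise kinematic templates:

* **Postural transitions** (sit-to-stand, stand-to-sit): raised-cosine
  angular-velocity pulses on the pitch channel integrating to +/-60
  degrees over 1.5 s, with low-frequency acceleration bumps.
* **Turns**: raised-cosine yaw pulses integrating to exactly 180
  degrees (peak 180 deg/s over 2.0 s by default); the closed-form pulse
  integral is the oracle for the segmentation tests.
* **Walking**: harmonic gait oscillation at 2 Hz (0.30 g vertical
  amplitude, anteroposterior fundamental plus a second harmonic,
  half-frequency mediolateral sway) and matching gyroscope oscillation.
* **Quiet stance**: band-limited (2 Hz low-passed, unit-SD-normalized)
  noise on the horizontal acceleration channels scaled to a 0.05 g sway
  SD (x1.3 with eyes closed), emulating postural sway.
* White Gaussian sensor noise on every channel (0.02 g / 2 deg/s SD).

Segment durations are jittered log-normally (sigma 0.05 per segment;
0.15 for cognitive TUG, mimicking dual-task cost). The template's exact
boundaries are recorded as ground truth.

Class effects are multiplicative shifts applied to minority
participants only: 1.5x transition duration, 0.7x peak turn velocity
(duration stretched to preserve the 180-degree turn), 1.5x sway power,
and an optional gait-harmonic amplitude multiplier (default 1). These
defaults produce a learnable but imperfect separation, which keeps the
classifier tests non-degenerate in both directions. `effect_tasks`
restricts the effects to chosen tasks; the planted-signal experiments
use `effect_tasks={"tug"}` so that discriminative information exists in
exactly one task group. `ClassEffect.scaled(s)` interpolates all
multipliers toward 1 for the effect-monotonicity experiments.

What the generator does **not** emulate: tremor, freezing of gait,
asymmetry, step-level gait events, gravity components, medication
state, disease progression, or any biomechanically realistic whole-body
dynamics. Passing tests therefore demonstrate that the pipeline
recovers the signal it is pointed at under the stated noise model — not
that the classifier reaches any particular accuracy on real patients.

## Segmentation

Complex tasks are decomposed via trapezoidal integration of angular
velocity. Candidate windows are seeded where the smoothed |angular
velocity| exceeds a high threshold (30 deg/s yaw for turns, 15 deg/s
pitch for transitions), merged across gaps shorter than 0.5 s, expanded
outward under a sign-consistent 1.5 deg/s low threshold (hysteresis),
and retained if the net integrated angle clears a minimum (90 degrees
for turns, 20 degrees for transitions). The smoothing window spans one
gait cycle (0.5 s at the 2 Hz cadence), which nulls the locomotor
oscillation that leaks into the pitch channel during walking. The first
transition in time is labeled sit-to-stand and the last stand-to-sit
(TUG protocol order — robust to sensor polarity). TUG/cogTUG yield the
canonical six segments (sit_to_stand, walk, turn, walk, turn,
stand_to_sit); the 32-foot walk yields its longest non-stationary,
non-turning span. Stationary samples are flagged by centered rolling
SDs (0.25 s window) below 0.08 g / 8 deg/s. A window that cannot be
decomposed raises a segmentation error and the recording's features
become missing values rather than silently wrong ones.

All thresholds live in `SegmentationParams`. On 100 synthetic TUGs the
median absolute boundary error is ~0.07 s (max ~0.13 s) against the
template truth.

## Feature registry

Each segment x channel yields exactly 84 features: 42 time-domain
statistics (moments, order statistics, crossing and peak rates,
first/second-difference statistics, autocorrelations at lags 1/5/10/25,
sample entropy, Hjorth parameters, crest/impulse/shape/margin factors,
histogram entropy), 22 spectral statistics from the one-sided DFT power
spectrum with a rectangular window over 0-20 Hz (moments, entropy,
flatness, dominant/median/95%-edge frequencies, four fixed band powers
plus their relative versions, low/high ratio, log-spectral slope,
peakiness), and the top 10 power amplitudes of the DFT and of the
Lomb-Scargle periodogram on a fixed 0.1-20 Hz grid (0.1 Hz steps). Each
segment additionally yields Pearson correlation, maximum normalized
cross-correlation magnitude, and the signal-magnitude-area ratio for
each of the 15 channel pairs (45 features). The registry is the
versioned name lists in `features.py`; counts (42/22/10/10/3) are
asserted at import time.

Two numerical choices worth noting. Sample entropy (m=2, r=0.2 SD,
Chebyshev distance) decimates series longer than 200 points to 200 on a
uniform grid; this bounds the quadratic template comparison and is part
of the registry definition. The Lomb-Scargle periodogram exploits the
uniform sample grid: the trig matrices and time-shift terms depend only
on (rate, length) and are cached, reducing each periodogram to two
matrix-vector products; the result is numerically identical to
`scipy.signal.lombscargle` (cross-checked in the tests).

For the two-trial tasks (TUG, cogTUG) every base feature appears four
times: trial 1, trial 2, trial mean, trial difference. Stance features
are computed on the whole window without segmentation. The default
five-task roster yields 27,999 columns, a deterministic function of the
segment structure. Preprocessing drops columns that are constant or
contain non-finite values on the fitted rows and imputes remaining
missing cells with fit-row medians; the fitted state is reusable on
held-out rows, so cross-validation never leaks test values.

## The MIEE classifier

MIEE (mutual-information feature selection for EasyEnsemble) addresses
the imbalance directly: five balanced subsets are drawn, each holding
every minority row plus an equal-size uniform draw (without
replacement) of majority rows; within each subset, features are ranked
by mutual information with the class label and the top 30 kept; a
1000-tree random forest is trained per subset (tests and the acceptance
script use 200 trees; the ensemble's behavior is insensitive to the
reduction at these subset sizes); prediction averages the five member
probabilities, with the minority class called at probability >= 0.5
(ties favor the rare class — imbalance-conservative).

Mutual information uses the nearest-neighbor estimator for a continuous
feature against a discrete label (Kraskov/Ross type, k=3), vectorized
across feature columns with a tiny deterministic jitter to break ties.
On shared inputs it agrees with sklearn's per-feature estimator to
machine precision while being ~100x faster on wide tables, which is
what makes per-subset selection over ~28k columns inside repeated CV
tractable. A feature duplicating a balanced binary label scores
ln 2 +/- 0.03 nats at n=24 (the digamma-estimator bias at that n).

Evaluation uses stratified 3-fold cross-validation repeated 5 times
with different seeds; preprocessing, selection and training all happen
inside the training fold. Each participant is scored exactly once per
repeat, and the final label is the majority vote over the five repeats
(an odd repeat count is enforced so the vote cannot tie). Held-out
participants excluded from training are scored by the trained ensemble
and placed as a percentile (weak ordering, so a maximum scores 100)
among reference participants assigned the same predicted class;
single-member or empty reference classes are flagged rather than
silently extrapolated.

## Evaluation statistics

PD is the positive class: sensitivity is PD recall, specificity non-PD
recall, balanced accuracy their mean, F1 uses PD as positive, and
AUC-ROC is the normalized Mann-Whitney U statistic of the averaged
probabilities. Confidence intervals come from the balanced bootstrap —
each class resampled with replacement at its own size, so every
replicate preserves the imbalance ratio and balanced accuracy stays
defined — with bias-corrected accelerated (BCa) adjustment, 10,000
replicates by default (`scipy.stats.bootstrap` with multi-sample
resampling; degenerate bootstrap distributions fall back to the
percentile interval with a flag).

Group permutation importance measures each mobility task's
contribution: all features of one task are permuted simultaneously with
the same row permutation (preserving within-group dependence) and the
mean decrease in balanced accuracy over 50 permutations is reported.
"Accuracy" here is balanced accuracy, consistent with the imbalance
rationale of the metric set. Selection tallies report the fraction of
selected features per task, subtask, and trial derivation pooled over
repeats x folds x subsets. Misclassification profiling compares correct
vs incorrect participants per class with pooled-variance two-tailed
t-tests (continuous) and Pearson chi-squared without continuity
correction (categorical; a flag enables the correction). Random-forest
proximity (fraction of trees in which two rows share a terminal leaf,
averaged over ensemble members on their own feature subsets) assigns
each query row the parkinsonism subtype with the highest mean
proximity.

## Baselines

The comparison arms run under the identical CV harness (same fold
seeds, preprocessing policy and metrics): (a) an unsupervised RF
ranking — real rows contrasted against a column-permuted shadow copy —
followed by a forward scan over the top-30 prefix maximizing the
training balanced accuracy, estimated out-of-bag because resubstitution
accuracy of a fully grown forest is identically 1; (b) a plain top-30
MI ranking; (c) a per-feature depth-2 decision-tree F1 ranking; (d) a
supervised RF ranking with a forward scan minimizing AIC, defined as
2k − 2 log L with L the binomial likelihood of the labels under
out-of-bag probabilities (forests define no native likelihood; OOB
deviance is the least-arbitrary choice) and k the subset size; and (e)
random undersampling to parity. Imbalance resampling combines the
Neighborhood Cleaning Rule (3-NN; majority rows misclassified by their
neighborhood, or neighboring a misclassified minority row, are removed
— never below class parity) with SMOTE (convex interpolation toward
k=5 minority neighbors up to parity), in three placements: sample
before selection and train on original data; sample before selection
and train on sampled data; select before sampling and train on sampled
data. Sampling never alters held-out test rows.

## Problem sizes in tests and the acceptance script

The desk-scale checks (metric arithmetic from the published confusion
matrices, filter gains, MI closed form, segmentation recovery on 100
TUGs, BCa coverage with 200 simulations at n=200) run at the sizes just
stated. The null calibration keeps the full 260:18 cohort and averages
cross-validated balanced accuracy over 10 CV seeds (3 in the acceptance
script) at 200 trees. The planted-signal and effect-monotonicity
experiments use scaled-down cohorts of 42:6 participants with
100-tree forests and common random numbers across effect levels —
chosen so the whole suite runs comfortably on a single CPU while
leaving the experiments' Monte-Carlo error well inside the asserted
margins.

## Known limitations

* The feature registry fixes a concrete, reproducible catalogue with
  the canonical counts; it is not a reconstruction of any particular
  published appendix list.
* The generator's effect sizes are stipulated design choices, not
  estimates from patient data; absolute classifier accuracies on
  synthetic cohorts say nothing about clinical accuracy.
* Segmentation assumes one TUG-shaped task per window (exactly two
  turns between the two transitions) and a roughly 2 Hz cadence for the
  gait-cancelling smoother; very slow or fragmented gait would need the
  exposed thresholds retuned.
* The percentile contract for held-out cases depends on the reference
  score distribution supplied by the caller; with tiny reference
  classes the percentile is reported but flagged.
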