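# Methods

This note documents the models, defaults, and design choices behind
pulse2stage, and what the synthetic validation does and does not show.

## Signal model and domain conventions

An IBI series is a strictly increasing sequence of beat timestamps
(seconds from recording start) with the interval (ms) that terminates at
each beat; timestamps and intervals must agree within 1 ms except across
explicit gap records. Hypnograms live on a 30-s epoch grid anchored at
lights-off; epochs are half-open `[t, t+30)` and an interval belongs to
the epoch containing its terminating beat. These conventions are
arbitrary but fixed, so exact tests are possible; nothing downstream is
sensitive to the choice beyond one-epoch boundary effects. Five-class
AASM labels are collapsed to four classes (N1, N2 → light; N3 → deep).

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes,
not realistic physiology in full.

* **Architecture**: first-order Markov chain over (wake, light, deep,
  REM) per 30-s epoch, built as `P = (1−a)I + a·1πᵀ` so the stationary
  distribution is exactly the target mix π = (0.10, 0.55, 0.15, 0.20) —
  light sleep a strict majority, consistent with a ~65–70% majority-class
  chance level — with `a = 0.12` giving mean bout lengths of a few
  minutes. Real hypnograms have cyclic ultradian structure that a
  first-order chain does not reproduce; the staging task here is
  correspondingly somewhat easier at equal feature quality.
* **Beats**: integrate-and-fire over an instantaneous mean-IBI signal:
  stage mean + very-low-frequency wander (amplitude = stage SDNN) + LF
  (~0.06–0.12 Hz) and HF (~0.20–0.33 Hz) oscillators + white beat-level
  jitter. Oscillator phases follow a random walk (0.2/0.4/0.6 rad·s^-1/2
  for VLF/LF/HF), making them narrowband processes rather than pure
  tones — as in real HRV, where respiratory sinus arrhythmia is coherent
  only over tens of seconds. Stage signatures (defaults): wake
  850 ms mean IBI with strong LF, light 1000 ms, deep 1100 ms with the
  strongest HF and least jitter, REM 950 ms with high variability. These
  satisfy the qualitative orderings the classifier exploits (wake has
  the fastest rate; deep sleep the strongest vagal HF component).
* **Artifacts** (defaults chosen once as plausible overnight failure
  modes; the real devices' artifact statistics are unknown): sensor
  detachments at 0.25/h lasting 10–30 min (beats deleted, gap recorded),
  movement-noise bursts at 0.2/h lasting 2–10 min (80 ms timestamp
  scatter), missed/extra beats at 1e-4 per beat (interval merge/split).
  The optical arm sensor gets higher rates than the chest belt; the
  reference ECG is near-clean. The ground-truth mask marks exactly the
  epochs whose signal was modified.
* **Devices and lag**: all devices share one true beat process; each
  wearable adds small timestamp noise (2 ms belt, 5 ms optical) and a
  uniform clock offset within ±120 s. Recordings overhang lights-off/on
  by 300 s, as manually started devices do.

Passing tests on this generator shows the pipeline recovers planted
structure under its stated assumptions. It does not show performance on
real recordings, where stage-conditional HRV differences are weaker,
subject-specific, and confounded by age, medication and arrhythmia; the
cohort covariates (age, gender, medication) are simulated but do not
modulate the signal model.

## Quality control

Eight candidate window features are computed on 10-min windows; the
shipped pipeline prunes them to 7 by permutation importance (mean
decrease in held-out balanced accuracy over 20 permutations, ties broken
by candidate order) and trains a 300-tree random forest (out-of-bag AUC
reported). Training labels come from the generator's truth masks: a
window is labeled bad when artifacts cover at least 30% of it — the
synthetic stand-in for manual labeling, whose real counterpart's rule is
unknown.

A window flag marks every overlapping epoch bad. With non-overlapping
windows this quantizes the mask to 20-epoch blocks; measured against
planted truth all false positives sat within 4 minutes of a real
artifact (boundary smear). The pipeline therefore classifies
*overlapping* windows (hop 120 s) and marks an epoch bad only when at
least a fraction `min_vote` of its covering windows are flagged; the
vote threshold is calibrated on the labeled training cohort by pooled
F1 over the grid 0.5–0.9 (the exposed analogue of adjusting the
detector's output threshold). This sharpens artifact boundaries to
roughly hop resolution (held-out epoch-mask F1 ≈ 0.9 vs ≈ 0.8 for the
tiling mask).

Masked epochs take the stage of the nearest clean epoch (ties to the
preceding epoch; leading runs take the first clean stage). A night is
unstageable when *strictly more* than 25% of epochs are bad — 25.0%
exactly is still stageable. Recording-level screening accumulates four
exclusion reasons — poor quality (>25% bad), unreadable, too short
(< 4 h by default), unsyncable — and the study report buckets each
excluded night under the first applicable reason in that order.

## Synchronization

Both IBI series are converted to instantaneous rate (60000/IBI at the
terminating beat, linearly interpolated to 4 Hz — standard HRV practice;
samples inside gaps hold the last value and are flagged). Raw rate
signals are dominated by slow stage structure, which makes the
cross-correlation peak broad and a peak-prominence confidence
uninformative; the implementation therefore removes a 25-s centered
moving average first, so the correlation peak is carried by the shared
beat-level fine structure and is sharp (width ~1 s). Per 600-s window
the normalized cross-correlation over ±120 s is maximized with parabolic
sub-sample refinement; the global lag is the median of window lags.
Confidence = (primary peak of the window-averaged correlation) / (largest
peak more than 2 s away); below 3.0 synchronization fails explicitly
(`SyncFailure`), the behaviour screening maps to "unsyncable". On
synthetic nights with default artifacts, recovered lags are within
~0.15 s of truth at confidence 5–8; two independent noise signals give
confidence ≈ 1. Clock drift (non-constant offset) is out of scope.

## Staging

Per-epoch features on a centered 11-epoch (5.5-min) context window:
mean IBI, SDNN, RMSSD, pNN50 over the pooled context intervals; LF
(0.04–0.15 Hz) and HF (0.15–0.40 Hz) band powers and their ratio from
the periodogram of the 4-Hz rate signal over the same span; an
is-imputed flag for epochs without own beats; age standardized as
(age − 50)/20 and gender (F=0, M=1). The context window carries the
temporal information that neighbouring epochs share.

The classifier behind the contract is
`GradientBoostingClassifier(n_estimators=120, learning_rate=0.1,
max_depth=3)`. Boosting stages double as selection checkpoints (every
10 stages): the **accuracy model** trains with uniform weights and keeps
the checkpoint with maximal validation accuracy; the **loss function
model** trains with inverse-frequency sample weights and keeps the
checkpoint minimizing the class-weighted cross-entropy
L = Σ w_{yᵢ}(−ln p_{i,yᵢ})/Σ w_{yᵢ} (weights normalized to mean 1, so L
is invariant to weight rescaling). Prediction at an intermediate
checkpoint walks `staged_predict_proba`. Argmax ties break in the fixed
order wake < light < deep < REM. Training requires all four stages in
train and validation sets; the validation split is by subject.

On the default synthetic cohort the loss-function model raises pooled
wake recall by ~3–4 points and deep recall by ~2–3 points relative to
the accuracy model, at the cost of light-sleep recall — the intended
bias correction. Known limitation: with this lightweight default model
the loss model's pooled κ runs 0.01–0.03 *below* the accuracy model's
(weighted-CE selection favours earlier, less overconfident checkpoints);
a stronger sequence model may not pay that price.

## Sleep parameters

Per night from the 4-class hypnogram (0.5 min per epoch): SOL = epochs
before the first sleep epoch; TST = sleep epochs; SE = TST/TIB × 100
with TIB the lights-off→lights-on span; WASO = all wake strictly after
the first sleep epoch up to lights-on (no terminal-wake exclusion — a
documented, configurable convention); deep and REM minutes. All-wake
nights return SOL = TIB with a flag. BAD labels must be imputed first;
SOL + TST + WASO = TIB holds identically.

## Agreement statistics

Differences are device − reference throughout (positive bias = device
overestimates). Bland–Altman: bias, LOA = bias ± 1.96·SD(d), with
standard CI approximations. SME is defined as SD(differences)/√n — the
standard error of the mean difference; this is the definition consistent
with the published agreement tables this module's arithmetic is checked
against, and it feeds MDC = SME·1.96·√2 (the 95% bound for a test–retest
difference). ICC(A,1) is the two-way random-effects, absolute-agreement,
single-rater form, computed from the ANOVA decomposition
(MS_R − MS_E)/(MS_R + MS_E + 2(MS_C − MS_E)/n) and categorized per
Koo–Li (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent);
identical zero-variance columns return 1 by convention, n < 3 is an
error. Cohen's κ comes from the confusion matrix (rows = predicted,
columns = true) and is undefined (None) when the chance agreement is 1.
Wilcoxon signed-rank uses exact enumeration for n ≤ 25 without ties and
the tie-corrected normal approximation otherwise, dropping zero
differences and flagging the all-zero case as degenerate; unpaired group
comparisons (e.g. medication vs none) use the Mann–Whitney rank-sum
test, since the design is unpaired.

## Pipeline and reproducibility

`run_study` simulates a training cohort (default 8 subjects × 1 night),
fits the QC detector and stager there, then processes each study night
per device: screen → sync → stage → QC mask → impute → sleep parameters,
aggregating pooled confusion/κ, the six-parameter agreement table per
device, and the exclusion log. QC runs *after* staging by design.
All randomness derives from one master seed via `SeedSequence`
spawning; reruns with the same config are byte-identical. Default study
sizes (10 × 2 nights, 8 training nights, 8-h nights) keep a full run in
a few minutes on one CPU; the test suite uses smaller cohorts (2–4
subjects, 3-h nights) with the same code paths.
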