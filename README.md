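# pulse2stage

Four-class sleep staging (wake / light / deep / REM) from heart-rate
variability, with the quality control and validation statistics needed to
trust the result. The package is aimed at sleep researchers who validate
wearable heart-rate sensors (ECG chest belts, optical PPG arm sensors)
against polysomnography (PSG), and at anyone who needs a reproducible,
inspectable pipeline from raw inter-beat intervals (IBIs) to sleep
parameters and device-agreement tables.

Because overnight wearable recordings are rarely shareable, the package
ships a first-class synthetic cohort generator with known ground truth
(stage-dependent IBI dynamics, device artifacts, inter-device clock lag),
so every stage of the pipeline can be validated end to end.

## What it implements

**IBI quality control.** Naive outlier interpolation misses whole stretches
of corrupted signal. Here, summary features on fixed 10-min windows
(median IBI, IQR, RMSSD, out-of-range fraction, large-successive-change
fraction, coverage deficit, lag-1 autocorrelation, max/min ratio, pruned to
7 by permutation importance) feed a random forest that classifies windows
good/bad. Bad windows become a 30-s-epoch mask; masked stage labels are
imputed from the nearest clean epochs; a night with more than 25% bad
epochs is unstageable.

**Imbalance-aware staging.** Light sleep dominates the night (predicting
it always can reach 65–70% accuracy), so two models are compared:

- *accuracy model* — trained with uniform weights, checkpoint selected by
  maximum validation accuracy;
- *loss function model* — trained with inverse-frequency sample weights
  w_c ∝ 1/f_c (normalized to mean 1) and selected by the minimum weighted
  cross-entropy L = Σᵢ w_{yᵢ}(−ln p_{i,yᵢ}) / Σᵢ w_{yᵢ},

the latter protecting recall of the minority stages (wake, deep).
The classifier is a pluggable contract; the default is gradient boosting
over per-epoch HRV features on a centered 11-epoch context window
(mean IBI, SDNN, RMSSD, pNN50, LF/HF band powers) plus age and gender.

**Synchronization.** Device and reference clocks are aligned by windowed
normalized cross-correlation of the 4-Hz instantaneous-rate signals
(high-pass detrended), median per-window lag, and a peak-prominence
confidence with an explicit failure mode for unsyncable recordings.

**Sleep parameters.** SOL, SE = TST/TIB × 100, TST, WASO, deep and REM
minutes per night from the 30-s hypnogram.

**Agreement battery.** Epoch level: confusion matrices (rows = predicted),
accuracy, Cohen's κ, per-class precision/recall/F1. Night level per
parameter: Bland–Altman bias and limits of agreement (bias ± 1.96 SD),
SME = SD(differences)/√n, minimal detectable change MDC = SME·1.96·√2,
two-way absolute-agreement intraclass correlation ICC(A,1) with Koo–Li
categories, Spearman's ρ, plus exact-small-n Wilcoxon signed-rank and
Mann–Whitney tests.

## Worked example

```python
from pulse2stage.cli_pipeline import RunConfig, run_study

cfg = RunConfig(seed=7, n_subjects=3, nights_per_subject=1,
                n_train_subjects=4, n_epochs=960)
report = run_study(cfg)
for dev, d in report["devices"].items():
    pooled = d["pooled"]
    print(f"{dev}: nights={d['n_analyzed']} accuracy={pooled['accuracy']:.3f} "
          f"kappa={pooled['kappa']:.3f}")
print("QC mask F1 vs planted artifacts:", report["qc_mask_pooled"]["f1"])
```

prints

```
ecg: nights=3 accuracy=0.830 kappa=0.742
h10: nights=3 accuracy=0.824 kappa=0.733
vs: nights=3 accuracy=0.779 kappa=0.675
QC mask F1 vs planted artifacts: 0.9023746702
```

i.e. on three simulated nights the pipeline recovers the reference
hypnogram with substantial chance-corrected agreement (κ 0.68–0.74,
highest for the clean reference-quality ECG signal, lowest for the noisier
optical sensor), and the QC detector localizes the planted artifacts with
F1 ≈ 0.90 at 30-s resolution. Each analyzed night also carries the
estimated clock lag, the bad-epoch fraction, and the six sleep parameters
for device and reference; `run_study` writes `report.json` and
`nights.csv` when given an output directory.

The same pipeline is scriptable from the shell:

```bash
pulse2stage simulate --subjects 2 --nights 1 --seed 5 --out cohort/
pulse2stage sync cohort/subject_000/night_0/ecg_ibi.csv \
                 cohort/subject_000/night_0/h10_ibi.csv
pulse2stage run-study --seed 7 --out results/
pulse2stage compare-modes --seed 7
```

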