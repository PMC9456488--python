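# ecgrobust

Robustness evaluation of ECG myocardial-infarction classifiers under
calibrated noise contamination.

## The problem

An automatic detector of myocardial infarction (MI) from the 12-lead
ECG is only clinically useful if its performance survives the
conditions of real recordings: baseline wander, muscle (EMG) artifact,
and electrode motion artifact. This package implements, as a tested
and reusable pipeline, a robustness protocol for beat-level NOR/MI
classification:

1. **Preprocessing** — per-lead min–max normalization onto [0, 1]
   (`x' = a + (x − x_min)(b − a)/(x_max − x_min)`), 8th-order low-pass
   Butterworth filtering (cutoff 0.04 × Nyquist, i.e. 20 Hz at
   1000 Hz), R-peak–anchored segmentation into 0.65 s beats
   (0.30 s before to 0.35 s after the R peak; 650 samples at 1000 Hz),
   and per-segment least-squares linear detrending.
2. **Inter-patient separation** — whole patients are assigned to the
   training group (G1: 27 per class) or the held-out group (G2: 26 per
   class); G2 segments are split 20 %/80 % into validation and test,
   stratified by class. No patient's beats ever appear on both sides.
3. **Classification** — SVM (C = 1, γ = 0.1, RBF), KNN (Euclidean,
   k = 5, inverse-distance weights) and random forest (800 trees,
   depth 25, min split 5) on the raw 650-sample beats, with no feature
   extraction; an optional successive-halving grid search (factor 3)
   over the published hyperparameter grids.
4. **Noise injection** — a noise trace n is mixed into a clean lead x
   as `x + k·n` with `k = sqrt(P_x / (P_n · 10^(SNR/10)))`, hitting the
   target signal-to-noise ratio exactly; the severity ladder is
   {16, 8, 2, −2} dB.
5. **Quality scoring** — MSE between clean and contaminated segments,
   plus approximate entropy ApEn(m, r) = Φ_m − Φ_{m+1} and fuzzy
   entropy FzEn(m, n, r) = ln Φ_m − ln Φ_{m+1} with exponential
   membership `exp(−d^n / r)` (defaults m = 2, r = 0.2 × SD, n = 2).
6. **Robustness curves** — accuracy and per-class precision/recall/F1
   over the {model × noise type × SNR} grid, plus clean and
   unfiltered-test baselines.

A fully seeded synthetic module (sum-of-Gaussians PQRST beats, MI
morphology via ST offset / pathological Q / T inversion, and the three
noise processes) makes the whole pipeline runnable end to end with no
data download; an adapter for WFDB-format records (the PTB/NSTDB
encoding) covers the real-data path.

## Worked example

The packaged reference tables carry the published row-normalized
confusion matrices of the clean and unfiltered test conditions,
together with the held-out segment counts (12,135 NOR, 10,755 MI, of
which 80 % — 9,708 and 8,604 — form the test set). Recomputing the
metric tables from those inputs:

```bash
$ ecgrobust evaluate --from-tables
 condition model class  precision  recall   f1  accuracy
     clean   SVM   NOR       0.75    0.78 0.76      0.74
     clean   SVM    MI       0.74    0.70 0.72      0.74
     clean   KNN   NOR       0.69    0.78 0.73      0.70
     clean   KNN    MI       0.71    0.61 0.66      0.70
     clean    RF   NOR       0.76    0.77 0.77      0.75
     clean    RF    MI       0.74    0.73 0.73      0.75
unfiltered   SVM   NOR       0.70    0.70 0.70      0.68
unfiltered   SVM    MI       0.66    0.66 0.66      0.68
unfiltered   KNN   NOR       0.66    0.69 0.67      0.65
unfiltered   KNN    MI       0.63    0.60 0.62      0.65
unfiltered    RF   NOR       0.72    0.61 0.66      0.67
unfiltered    RF    MI       0.62    0.73 0.67      0.67
```

Read: on the clean inter-patient test set the random forest is the
strongest model (accuracy 0.75); removing the Butterworth stage costs
every model 4–9 accuracy points, with RF degrading the most. (Three
cells differ by 0.01 from the originally published tables because the
published confusion fractions are themselves rounded to two decimals;
see `docs/methods.md`.)

The full synthetic experiment — generate a cohort, preprocess, train
on clean G1 beats, and sweep noise type × SNR on the held-out test
beats:

```bash
ecgrobust sweep --n-per-class 8 --g1-per-class 5 --seed 0 --out sweep.csv
```

writes the long-format degradation grid (model, noise, snr_db, class,
precision, recall, f1, accuracy). On the default synthetic cohort all
three models are perfect at 16 dB and degrade monotonically toward
−2 dB (e.g. at seed 0: SVM falls to ≈ 0.50 under muscle artifact while
KNN stays ≈ 1.00 — high-frequency noise barely moves beats in
Euclidean distance, but shifts the SVM's kernel values).

Library use mirrors the CLI:

```python
from ecgrobust import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=0))
result.split.assert_inter_patient()      # train/test patients disjoint
print(result.report.to_frame().head())
```

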