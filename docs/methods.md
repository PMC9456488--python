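# Methods

This note documents the models, conventions and design choices behind
`ecgrobust`, in the order the pipeline runs.

## Synthetic cohort model

Each beat is a sum of five Gaussians (P, Q, R, S, T), centered at
(−0.17, −0.035, 0, 0.035, 0.25) s relative to the R peak with widths
(25, 10, 12, 12, 45) ms and normalized amplitudes
(0.15, −0.08, 1.00, −0.20, 0.35). Beats repeat at the RR interval of a
per-patient heart rate drawn uniformly from 60–90 bpm, with ±5 %
uniform per-beat RR jitter (seeded) so segmentation stays nontrivial.
The first beat is scheduled at RR/2, so a 60 bpm, 10 s record holds
exactly 10 beats. Records default to 32 s per lead at 1000 Hz
(32,000 samples), though tests and the demonstration pipeline use
shorter records.

MI morphology is emulated with the three ECG hallmarks of infarction,
each patient expressing a random non-empty subset (each hallmark
included with probability 0.6):

* **ST-segment offset** — a raised-cosine-edged plateau of height
  `st_offset` (sign random, magnitude U(0.15, 0.30) relative to the
  unit R amplitude) spanning 0.06–0.16 s after R, flat across the
  0.08–0.12 s measurement window, emulating ST elevation/depression;
* **pathological Q** — Q amplitude −U(0.30, 0.50) × R, beyond the 25 %
  diagnostic threshold;
* **T inversion** — T amplitude flipped negative and rescaled by
  U(0.8, 1.2).

Because the subset is random, no single feature separates the classes.
Per-patient morphology jitter multiplies wave amplitudes and widths by
N(1, 0.10); leads beyond the reference lead 0 are amplitude-scaled
(U(0.6, 1.1), sign-flipped with probability 0.25) variants with
per-beat, per-wave amplitude jitter of sd 0.05. True lead-field
physics is out of scope: the 12 leads are correlated views of one
source, which matches how the pipeline treats them (each lead-beat is
an independent classifier sample) but does not reproduce real
inter-lead morphology. Jitter magnitudes are a package choice —
chosen once as plausible beat-to-beat variability — not calibrated to
PTB; synthetic classes are considerably easier to separate than real
PTB patients, so pipeline accuracies on synthetic cohorts sit well
above the published real-data level and passing tests demonstrate
mechanical correctness and qualitative degradation behavior, not
clinical performance.

The three noise processes emulate the ambulatory-ECG noise families of
the NSTDB recordings: baseline wander is a sum of six sinusoids with
frequencies U(0.05, 0.45) Hz and random phases; muscle artifact is
white noise band-passed to 20–200 Hz; electrode motion is a Poisson
train (rate 0.5/s) of Laplace-amplitude steps smoothed to ~50 ms
transients plus a sub-0.3 Hz drift. All realizations are exactly
zero-mean and unit-variance before SNR scaling, and every generator is
a pure function of its seed.

## Preprocessing conventions

* **Cutoff interpretation.** The low-pass cutoff 0.04 is read as a
  fraction of Nyquist (20 Hz at 1000 Hz), the standard DSP convention;
  a 0.04 Hz low-pass would erase all cardiac content. An absolute-Hz
  constructor is provided.
* **Zero-phase default.** The filter is applied forward–backward by
  default so R-peak positions are not delayed; this squares the
  magnitude response (−6 dB rather than −3 dB at the cutoff). A causal
  single-pass mode is available.
* **R-peak detection** follows the Pan–Tompkins recipe (band-pass
  5–15 Hz, derivative, squaring, 150 ms moving-window integration,
  thresholded peak picking with a 200 ms refractory period), refined
  to the local extremum of the band-passed signal. On synthetic
  records a flag substitutes the generator's ground-truth peaks, which
  decouples detector error from downstream tests; the end-to-end
  pipeline uses ground truth by default for exactly that reason.
* **Detrending is per-segment**, not per-record: the least-squares
  line of each 650-sample window is subtracted after slicing. Edge
  beats whose window crosses a record boundary are dropped, never
  padded; drops are logged so segment accounting stays auditable.
* Min–max normalization of a constant lead raises a degenerate-input
  error rather than silently dividing by zero.

## SNR mixing

SNR is defined on mean squared amplitude over the trace being mixed
(`SNR = 10·log10(P_signal/P_noise)`), noise window mean-removed before
power measurement, scale `k = sqrt(P_s/(P_n·10^(SNR/10)))`. Mixing is
exact to float precision (measured error < 1e−12 dB in practice,
asserted < 1e−9). In the sweep, each preprocessed test segment is
mixed independently with a seeded window of one noise realization per
(noise kind, SNR) cell; segments are not re-filtered afterwards — the
point of the protocol is to measure the trained models on degraded
inputs. The severity ladder {16, 8, 2, −2} dB is configurable.

## Entropy conventions

Several conventions in the fuzzy/approximate entropy literature are
internally inconsistent across sources; the package pins:

* **Distance**: Chebyshev for both ApEn and FzEn (the canonical
  choice), with a Euclidean option.
* **Tolerance**: r = 0.2 is interpreted as 0.2 × SD of the analyzed
  series (`sd_relative`), making both measures amplitude-invariant;
  absolute mode available. For a constant series any positive
  tolerance yields the same entropy (0), which is what the
  implementation returns.
* **ApEn**: self-matches included, Φ_m averaged over N−m+1 templates
  with denominator N−m+1 (the classic definition); ApEn(constant) = 0.
* **FzEn**: templates baseline-removed, self-matches excluded, the
  same N−m templates used at both embedding orders, outer
  normalization 1/(N−m) and inner 1/(N−m−1) — the standard
  fuzzy-entropy normalization. Published variants disagree on these
  constants; the brute-force oracles in the test suite freeze this
  choice.

Entropies are computed per segment (not per record); per-class means
versus SNR form the machine-readable analogue of the quality curves.

## Classifiers and search

Training is delegated to scikit-learn; this package owns the
contracts, the final hyperparameter sets, and the search protocol. The
final SVM setting C = 1 lies outside the search grid's C ∈ {10, 100};
both are kept exactly as printed in the source protocol (defaults
honor the final set, the grid stays the grid). The successive-halving
search uses a fixed train/validation split (PredefinedSplit), factor
3, with the sample count as the resource; 9 candidates shrink
9 → 3 → 1. Ties resolve to the earliest grid entry.

## Evaluation conventions

* The 20/80 validation/test split is segment-level within the held-out
  group, stratified by class and seeded. Only this reading makes the
  published test counts (9,708 = 0.8 × 12,135 and 8,604 = 0.8 ×
  10,755) come out exact; inter-patient separation concerns train
  versus held-out, which is preserved and asserted on every run.
* Metrics for table comparison are rounded half-up to 2 decimals; raw
  doubles are retained everywhere else.
* A zero denominator (e.g. a model that never predicts one class)
  reports the affected metric as 0 with a logged warning.
* **Published-table consistency.** Recomputing the published metric
  tables from the published row-normalized confusion matrices
  reproduces 45 of 48 cells exactly. Three cells (clean SVM MI
  precision, unfiltered KNN MI F1, unfiltered RF accuracy) land 0.01
  away: the published fractions are themselves rounded to two
  decimals, and exact arithmetic on them provably cannot recover the
  originally printed value (e.g. any MI recall that prints as 0.70
  forces an MI precision ≥ 0.7368, which prints as 0.74, not the
  published 0.73). The cross-check asserts exact equality where
  arithmetic permits and the derivable value (within one printed unit)
  for those three cells.

## Problem sizes

The demonstration pipeline and the acceptance script run a reduced
cohort — 8 patients per class (5 training), 3 leads, 16 s records —
which the package treats as its default experiment scale; a full
53-patients-per-class, 12-lead, 32 s configuration is a parameter
change. Degradation behavior (monotone accuracy loss toward −2 dB,
above-chance floors) is scale-free and is verified over 5 seeds.

## Known limitations

* The synthetic generator does not model arrhythmias, HR extremes,
  pediatric morphology, real inter-lead physics, or PTB's
  beat-morphology variability; it is a correctness harness, not a
  simulator of record.
* The WFDB adapter implements only single-`.dat`, format-16 records —
  sufficient for round-tripping the package's own writer and reading
  PTB-style records, not a general WFDB implementation. WFDB is an
  integer format: writing quantizes at the ADC step (1/gain).
* Composite simultaneous noises and time-varying SNR schedules are out
  of scope, as are significance tests between models.
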