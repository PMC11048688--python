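# Methods

## Problem and pipeline

The package discriminates Alzheimer's disease (AD), frontotemporal dementia
(FTD) and healthy controls (HC) from 19-channel (10–20 montage) resting-state
EEG sampled at 500 Hz. Recordings are cut into overlapping 1 s windows; each
window is reduced to one scalar per channel by a complexity measure; the
resulting feature rows are classified per window by a fixed-hyperparameter
learner; evaluation is strictly subject-disjoint. Three binary tasks are
studied: AD-vs-HC, FTD-vs-HC, AD-vs-FTD, with the disease (AD in AD-vs-FTD)
as the positive class.

## Synthetic cohort

Because patient EEG cannot ship with the package, a generator produces
labelled recordings carrying the statistical structure the analysis assumes.
Each channel is the sum of:

* **1/f background** — Fourier-shaped noise with spectral exponent 1.0
  (configurable), band-limited to 0.5–45 Hz, RMS 2 µV;
* **band oscillations** — narrowband Gaussian noise (4th-order Butterworth
  band-pass of white noise, 10 s warm-up discarded so the slow delta edge is
  settled) in delta (0.5–4 Hz, 6 µV RMS), theta (4–8, 5), alpha (8–12, 10,
  scaled 0.6–1.4 front-to-back so HC alpha is posterior-dominant) and beta
  (12–30, 1);
* **sensor noise** — white, 0.7 µV RMS;
* a per-subject gain jitter of ±10%, so windows from one subject correlate
  and subject-level leakage is detectable by the test suite.

Group effects are band-power multipliers: AD ×1.8 delta/theta and ×0.6
alpha, global; FTD ×1.6 delta/theta confined to the frontal electrodes (sigmoid falloff in the anterior–posterior coordinate, weight
≈ 1 at Fp1/Fp2, ≈ 0.1 at the central row); HC is the reference.
Oscillations are noise-like rather than sinusoidal on purpose: pure tones
make several complexity measures degenerate across windows.

The default cohort is 36 AD / 23 FTD / 29 HC subjects; the *study* scale
used by the tests and the acceptance script is 10 subjects per group at 60 s
per recording, which keeps the full three-task, two-overlap, five-seed study
under a minute of feature extraction and classification on one CPU.

The baseline amplitudes above are a design requirement of the generator, not
physiology: they were chosen once so that the fixed group multipliers yield
the documented spectral orderings (posterior alpha/delta ratio HC > AD;
frontal delta raised in FTD) *and* make the three tasks learnable from 1 s
windows without being trivial — the resulting subject-disjoint test
accuracies (≈0.99 / 0.86 / 0.93 for AD-HC / FTD-HC / AD-FTD with SVD
entropy + KNN) sit in the range reported for real cohorts. What passing
tests show is therefore that the *pipeline* extracts and classifies the
planted structure correctly; they say nothing about effect sizes in real
patients, where inter-subject variability is far larger and artifacts exist.

## Feature conventions

All five measures are implemented from their defining formulas; the table
extractor runs vectorised batch kernels that are checked cell-by-cell
against the scalar definitions.

* **SVD entropy** — delay embedding with order M = 3, delay 1 (the common
  default of EEG feature libraries; the analysis keeps it fixed); singular
  values via eigenvalues of the 3×3 Gram matrix, zeroed below 1e−7 of the
  largest so rank-deficient embeddings (constant windows) give exact
  entropies; entropy in bits, *not* normalised by log₂ M. Bounded by
  log₂ 3 ≈ 1.585.
* **Higuchi FD** — kmax = 10; curve lengths L_m(k) use the standard
  normalisation (N−1)/(⌊(N−m)/k⌋·k) per start phase m; D is the slope of
  ln L(k) against ln(1/k), unweighted least squares over k = 1..kmax. A
  window whose curve length vanishes at every scale (flat line) returns
  1.0 by convention.
* **Zero-crossing rate** — strict product test sₜ·sₜ₋₁ < 0 divided by
  T−1. Exact-zero samples break crossings; the measure is documented as
  sampling-phase-sensitive (a 10 Hz sine sampled for 1 s at 500 Hz with
  phase 0.1 rad has 19, not 20, strict sign changes).
* **DFA** — integrate the mean-centred window, split into non-overlapping
  boxes (trailing partial box discarded) at 12 log-spaced integer scales in
  [4, w/4] (duplicates removed), subtract a per-box first-order polynomial
  fit, F(n) = RMS of the residuals, α = slope of log F vs log n. A scale
  with F(n) = 0 (exactly polynomial signal) is an error naming the scale.
* **Hjorth** — activity = variance (µV²); derivative = first difference
  with no sampling-rate scaling, so mobility and complexity are per-sample
  and dimensionless; collapsed to one column as (mobility + complexity)/2
  so every measure yields the same 19-column layout. Both raw parameters
  stay available through `hjorth()`.

Windows are 0-based, half-open, with step = round(w·(1−overlap)); at the
study's 500-sample windows the 50% and 90% overlaps give exact steps of 250
and 50 samples and ⌊(N−w)/step⌋+1 windows. Rows whose extraction is
undefined on any channel (e.g. Hjorth on a constant channel) are dropped
with a logged count.

## Resampling protocol

Splitting is at subject level, stratified by group, 80:20 with ties rounded
toward training; the 15 cross-validation folds partition the *training
subjects* round-robin per class, so fold validation sets are
subject-disjoint from their fit sets. SMOTE (k = 5 neighbours, Euclidean
distance over the feature columns) runs strictly after splitting, on
training rows only, balancing the two classes by interpolated minority rows;
synthetic rows carry a sentinel subject id and can never reach a validation
or test set. Test windows are never resampled.

## Learners and metrics

KNN is implemented natively (k = 6, uniform weights, Euclidean); a 3–3 vote
tie is broken toward the class of the single nearest neighbour, and the
positive-class score is the positive fraction among the k neighbours.
Random Forest and Extra Trees (scikit-learn) and XGBoost are configured to
the study's fixed hyperparameters; re-implementing tree ensembles is not
this package's contribution. All evaluation metrics are native: confusion
counts; sensitivity, precision, accuracy and F1 with undefined ratios
reported as `None` rather than 0; AUC by the Mann–Whitney rank statistic
with midpoint tie handling, checked in the tests against an O(n²) pairwise
oracle and scikit-learn.

## The window-overlap comparison

Increasing the window overlap from 50% to 90% quintuples the number of
windows but makes consecutive windows share 90% of their samples. How this
affects measured accuracy depends entirely on the cross-validation
granularity, and the package exposes both so the effect can be studied:

* with **row-stratified 15-fold CV** (`cv_unit="window"`, the historically
  common construction), validation windows find near-duplicates of
  themselves in the fit folds; CV accuracy for SVD + KNN rises from
  ≈0.94 at 50% overlap to ≈0.997 at 90% (a +5.4 point "gain" on the
  synthetic study cohort);
* with **subject-held-out folds** (`cv_unit="subject"`, the default) and on
  the subject-disjoint test set, the same comparison shows no gain
  (−1.0 and −0.3 points respectively on the same cohort): denser windows
  of the same recordings add almost no independent information, and the
  near-duplicate training neighbourhoods slightly blunt a k = 6 vote.

The default protocol therefore treats window-level CV scores as an upper
bound inflated by window-level leakage, and reports subject-disjoint test
metrics as the headline numbers. `analysis/03_run_classification.py` prints
the full comparison.

## Channel importance and topomaps

Importance is the tree ensemble's normalised impurity importances mapped to
channels (permutation importance — mean accuracy drop per shuffled channel,
negatives clipped — covers models without importances). Rankings break ties
by montage order. Topomaps interpolate the 19 scores with a thin-plate
spline over the unit head disc (electrode coordinates are an
azimuthal-equidistant projection of the 10–20 positions); the interpolation
method is a rendering choice with no analytic weight.

## Numerical and degenerate-input conventions

Constant windows: SVD entropy 0, Higuchi FD 1.0, ZCR 0, Hjorth an error
(mobility undefined), DFA an error (zero fluctuation). Non-finite samples
are rejected everywhere. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; cohort generation, splits, SMOTE and
tree learners are bit-reproducible given their seeds.

## EDF/BIDS interchange

Synthetic cohorts are written as plain 16-bit EDF (physical range declared
per file, 1 s data records) in a minimal BIDS layout
(`sub-XXX/eeg/sub-XXX_task-eyesclosed_eeg.edf` plus `participants.tsv`
mapping participants to groups; single-letter group codes are accepted on
read). Reading uses MNE; subjects missing montage channels are rejected
with a logged reason while the run continues. Round-trip error is bounded
by the 16-bit quantisation step. The optional band-pass (0.5–45 Hz
zero-phase Butterworth, order 6 per pass — chosen so mains-band content at
60 Hz is attenuated below 5% amplitude after the double pass) defaults to
on for real BIDS input and off for synthetic cohorts, which are generated
band-limited; the slow 0.5 Hz edge rings near recording boundaries, which
stretched reflection padding tames but cannot remove.

## Known limitations

* The generator has no artifacts, no dipole geometry, no inter-channel
  correlation beyond shared spatial weighting, and inter-subject
  variability limited to gain jitter; real-data accuracies and channel
  rankings will differ.
* Per-window classification treats windows as exchangeable; no
  subject-level aggregation of predictions is performed (by design, to
  mirror the windowed protocol).
* FTD-vs-HC is the hardest synthetic task (frontal-only contrast) and its
  accuracy is the most seed-sensitive; the test suite asserts means over
  five seeds.
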