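# Methods

This note documents the models and procedures implemented in
`megstates`, the parameters that matter, the synthetic-data model and
its limits, and the numerical and design choices made where the design
was genuinely open.

## States, epochs, and the rejection rule

Two internal states are operationalised around each reported perceptual
switch: the *transition* state as the `T` ms window immediately before
the button press, and the *maintenance* state as a `T` ms window
starting `offset` ms after it.  Equal window lengths keep the two
classes at the same feature dimension.  The reaction time (the lag
between the endogenous switch and the press) means the transition
window is chosen long enough (600–1800 ms) to contain the switch.

Windows are half-open `[start, end)` in sample space; the press sample
belongs to the maintenance side, making the two windows disjoint at
offset 0.  An event is rejected when its maintenance window strictly
overlaps the next event's transition window or its transition window
overlaps the previous event's maintenance window; a shared endpoint is
not an overlap.  Because the sources are ambiguous about which event of
an offending pair to drop, *both* are dropped — conservative, and it
keeps the classes paired.  Events whose windows would leave the block
are likewise rejected (our addition; block edges are otherwise
unspecified).  The overlap predicate is monotone in `T`: shrinking the
window never rejects more events.

For the temporal-evolution analysis, rejection can be computed against
the full `[press, press + horizon)` zone (`rejection_horizon_ms`) so
that all seven shifted subwindows share one retained-event set.

## Wavelet band-energy features

The feature path implements a complex Morlet analysis:
`cmw(t, f) = A·exp(−t²/2s²)·exp(i2πft)` with peak amplitude
`A = 1/(s√π)^{1/2}`, evaluated on a logarithmic grid of 40 frequencies
spanning 1–80 Hz at 1000 Hz sampling.  Coefficients are the sliding
inner product of signal and kernel; squared magnitudes are averaged
over the grid bins of each canonical band, over sensors at the chosen
spatial scope, and over `L` contiguous temporal segments.

Open parameters and their settings:

* **Gaussian width** `s(f)`: not specified by the formulation; we use
  the standard constant-cycles choice `s(f) = n_cycles/(2πf)` with
  `n_cycles = 7` (configurable), balancing time and frequency
  resolution across 1–80 Hz.
* **Grid size**: 40 log-spaced frequencies (configurable), which leaves
  at least two bins in the narrowest bands (theta, alpha).  A band with
  no bins raises an error naming the band.
* **Edge handling**: epochs are reflection-padded by the longest kernel
  half-length (4 standard deviations) needed by the requested bands,
  and padded samples are discarded before segment averaging.  For the
  delta band at 1 Hz the half-kernel (~4.5 s) exceeds any epoch, so the
  pad is capped at one sample short of the epoch length; delta-band
  energies on short epochs are therefore smoothed estimates, as any
  method's would be at that time–frequency product.
* **Segment averaging** uses every sample of a segment (no
  subsampling).

Spatial scopes: *global* (mean over all retained sensors), *left/right
hemispheric* (sign of the lateral coordinate; midline sensors within a
configurable tolerance belong to neither hemisphere and are excluded
from hemispheric averages), *local-10* (mean per Ward cluster), and
*source-89* (no averaging — each region series is kept).  The 36
sensors over the sensorimotor strip are excluded before any averaging,
to keep motor preparation/execution out of the features.  Ward
clustering of the 10 local regions runs on Euclidean distances between
3-D sensor positions (scipy's Lance–Williams implementation) and is
deterministic for a given layout.

The Welch-PSD baseline uses 500 ms sub-windows with 50% overlap
(configurable; unspecified in the formulation), band-averages the
periodogram, and performs no temporal segmentation: 10 × 4 features.

All features scale as amplitude²; the pipeline standardises per
training fold, so analyses are scale-invariant.

## Reduction and selection

*PCA route* (sensor space): features are standardised with
training-fold mean/SD — band powers span orders of magnitude, and both
RBF kernels and F-ratios are scale-sensitive — then projected onto the
leading principal components capturing `C_v`% of training variance.
`C_v` is chosen on an inner 10-fold cross-validation over
{95, 96, 97, 98, 99, 99.5, 99.9}% (the stated range endpoints,
discretised by us), ties toward the smaller retained dimension.  Outer
test rows never reach any fit.

*F-ratio route* (source space): each feature's F-ratio is the ratio of
between-class to total within-class variance (affine-invariant; a
zero-within-variance feature with distinct means ranks first via an
infinity sentinel).  The top-`k` features are kept, ties to the lower
feature index.  How many features to select is unstated; `k` is chosen
on an inner 10-fold CV over the geometric grid {8, 16, 32, 64, 128},
mirroring the PCA-grid approach.  Selection reports aggregate the
marginal distribution of selected features over bands and regions per
fold and averaged across folds.

When a training partition is too small to split (fewer than two
samples of a class), the PCA route keeps the largest grid `C_v` and the
selector the smallest grid `k` — degenerate-data fallbacks only.

## Classifiers, metrics, chance

Two classifiers: an RBF-kernel SVM, and an MLP with 10 hidden tanh
units trained to a 1e-5 error goal, capped at 2000 iterations.  The MLP
uses scikit-learn's lbfgs solver — a batch quasi-Newton rule, the
closest available analogue of scaled-conjugate-gradient
backpropagation.  SVM regularisation can be tuned by an inner 5-fold
grid search over C ∈ {0.1, 1, 10} with the 'scale' kernel-width
heuristic (`ClassifierSpec(tune=True)`); inside the `C_v`/`k`
inner-selection loops a fixed (C = 1, 'scale') SVM scores the grid to
keep the nesting tractable on one CPU.

Evaluation is stratified 10-fold cross-validation with a fixed shuffle
seed; trials are pooled across subjects without per-subject grouping
(no personalised models, matching the pooled design).  Transition is
the positive class: sensitivity is transition recall, specificity
maintenance recall, and per fold
`accuracy = (sens·n_trans + spec·n_maint)/n` holds exactly.  Accuracy
is reported with its across-fold SD and compared against the empirical
chance level: the smallest accuracy `a` with
`P[Binomial(n, ½) ≥ a·n] < 0.05` (strict inequality on the survival
function), which is > 50% for finite n and decreases toward 50%.

Hemispheric fusion combines per-sample continuous scores
`S_f = p·S_l + (1−p)·S_r` for p = 0…1 in steps of 0.1.  "Score" is the
signed SVM margin or the MLP class-probability difference, both
oriented positive-means-transition and thresholded at zero, so the
p = 0/1 endpoints reproduce the single-hemisphere results bit-for-bit.

Class imbalance (the 7× maintenance surplus of the temporal-evolution
design) is addressed by random majority subsampling: each repeat draws
a majority subset the size of the minority class without replacement,
cross-validates, and metrics are averaged over repeats; per-offset
detection is reported from the out-of-fold predictions.

Band-wise transition-vs-maintenance comparisons are paired t-tests on
whole-epoch mean band power (pairing by event is implied by the
reported degrees of freedom: n pairs give df = n − 1), Bonferroni
corrected at 0.05/6 ≈ 0.0083 over the six bands.

Cross-conditional evaluation trains on one stimulus factor (NC, SAM,
SFM; presentation modes pooled) and tests on the others; all model
selection happens on the training stimulus, and the 3 × 3 matrix marks
the diagonal "Training".

## The synthetic generator

The generator emulates the study design: 11 subjects × 6 conditions
(3 stimulus types × continuous/blanking) × 3 repetitions of 60 s blocks
from 160 sensors at 1000 Hz, with 36 sensors flagged over a central
sensorimotor band.  Its components:

* **Events**: inter-switch intervals are gamma-distributed (shape 2)
  with condition-specific means derived from the per-condition switch
  totals of the study's trial table (NCC 5.4 s … SAMB 37 s), scaled per
  subject by a lognormal factor (σ = 0.8) to reproduce the heavy
  between-subject rate variability.  Reaction times are lognormal with
  ~300 ms median (σ = 0.35), capped at 600 ms — below the shortest
  transition window, so the switch always falls inside it.
* **Background**: band-limited (1–80 Hz) Gaussian noise with a 1/f
  spectrum (exponent 1.0), independent per channel, unit RMS; units are
  arbitrary (all analyses are normalised, so femtotesla scaling is not
  modelled).
* **State effect**: for the posterior quarter of retained sensors (and,
  in source space, a fixed parietal/occipital/cerebellar region set),
  the background is decomposed into the six canonical bands and each
  planted band is multiplied by `sqrt(1 + e_b·w(t))`, so in-window band
  power is exactly `(1 + e_b)` times baseline in expectation.  In
  'window' mode `w = 1` on `[true_switch, press + 0.1 s)`.  Effect
  sizes are free parameters (the sources report only test statistics,
  not effect sizes, and synthetic effects are deliberately not
  calibrated to reported accuracies); defaults are alpha 0.8, beta 1.0,
  lower gamma 1.0, upper gamma 0.8 — largest in the bands with the
  strongest reported statistics.
* **Drift mode**: `w` ramps linearly over `drift_len` s before the
  switch, holds 1 through the press and for `jolt_hold = 0.5` s after
  it, then decays exponentially (`jolt_tau`).  This emulates
  switch-related activity building up before the report and a
  post-press jolt decaying after ~500 ms, and produces the
  rise-then-fall maintenance-detection profile: earliest subwindows are
  contaminated by the jolt, late subwindows by the next switch's
  build-up.
* **Stimulus component**: narrowband (5–7 Hz) noise added to the
  posterior sensors; under blanking it is gated 3 s on / 3 s off
  (gating the added component, not the background).
* **Determinism**: a single integer seed drives everything through
  `numpy.random.SeedSequence` spawn keys per (subject, condition,
  repetition), so identical configurations give identical datasets and
  any block can be regenerated in isolation.

Datasets stream block-by-block (a full-scale dataset is ~15 GB dense)
and can be serialised to a self-describing HDF5 container with embedded
layout, events, and generator configuration; event tables export as
TSV.

**What the generator does not model** — and hence what passing tests do
not show about real data: no head geometry or forward/inverse physics
(sensor topographies are a literal posterior subset, not field
patterns), no cross-channel covariance beyond the shared stimulus
component, no artifacts (blinks, saccades, cardiac, line noise), no
non-stationarities other than the planted state effect, and Poisson-like
rather than empirically-shaped switch dynamics.  Pipeline accuracies on
synthetic data therefore validate the machinery — leakage-free model
selection, calibration, recovery of planted structure — not the
decodability of real recordings.  The source generator likewise stands
in for beamformer reconstruction; its 89 region labels follow the AAL
naming convention, with a motor-related exclusion list of our own
construction (the precise 27 excluded regions are not recoverable from
the available text).

## Problem sizes

Tests and examples run the same code paths at reduced scale — typically
12–32 sensors at 250–1000 Hz, one to five subjects, 40–60 s blocks,
yielding 90–230 epochs — chosen so the statistical structure (event
density, class balance, effect topography) matches the full-scale
defaults.  The acceptance properties (chance calibration over 50 null
runs, three-level effect-size monotonicity, selection enrichment at
≥ 2× the uniform share, the rise-then-fall profile) are all computed at
these sizes with fixed seeds.

## Known limitations

* The MLP's training rule approximates, not replicates, SCG
  backpropagation; per-fold retained dimensions and accuracies are
  reproducible but solver-specific.
* Delta/theta band energies on ≤ 1.8 s epochs carry few independent
  time–frequency samples; they are included for completeness (source
  analyses use all six bands) but are intrinsically smooth.
* The empirical chance level assumes exchangeable trials; pooling
  epochs across subjects (as the pooled design does) slightly
  understates dependence between trials of one subject.
* `fuse_scores` thresholds fused scores at zero; classifiers whose
  scores are not centred on zero would need recalibration before
  fusion.
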