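# Methods

This note records the modelling assumptions, numerical choices, and
design decisions behind the package, and what the synthetic data can and
cannot establish.

## Synthetic uHD-EEG generator

The generator emulates a cued finger-extension session: each run opens
with a 30 s baseline, then alternates rests (uniform 3–4 s, rounded to
whole samples so the event bookkeeping closes exactly) with 5 s task
periods; each of the five fingers is cued `trials_per_run / 5` times in
a shuffled order. Default geometry is the full 16 × 16 grid at 8.6 mm
pitch and 600 Hz sampling; tests and examples use smaller grids with the
same pitch and rate.

Signal model per channel, in units of the background-noise SD:

* **Background**: Gaussian noise with a 1/f power spectrum (spectral
  exponent 1), per-channel SD `noise_sd = 1`. This reproduces the
  broadband spectral tilt of EEG without any fitted parameters.
* **Class sources**: one unit-SD band-limited Gaussian oscillator per
  finger, mixed through a Gaussian spatial patch (`patch_sigma_mm = 10`)
  centred on adjacent grid cells along the middle row (falling back to
  the grid diagonal on grids narrower than five columns). The oscillator
  is always present at amplitude `source_amp = 0.5`; during that
  finger's task periods its envelope rises to `1 + effect_size` — an
  event-related synchronisation. Each finger uses its own rhythm (mu,
  beta, low gamma, high gamma, super-high gamma) so classes separate in
  both the spatial and spectral feature axes. With `effect_size = 0` the
  envelope never moves and the class-conditional signal distributions
  are identical by construction.
* **Line noise**: coherent sinusoids at 60 Hz and harmonics up to
  240 Hz, amplitude `line_amp / k` for harmonic k, random phase per run.
* **Artifacts**: Poisson-distributed 50 ms Hann-windowed transients of
  ±20 noise-SD, at `5e-5` per channel-second — roughly one every few
  channels per run, so that the >10% bad-channel run-rejection rule
  trips only on genuinely contaminated runs. The source amplitude of
  0.5 keeps task oscillation peaks below the |z| > 6 artifact threshold
  for effect sizes up to about 2.5; far stronger effects would begin to
  be screened out as artifacts, which is a property of the screening
  rule, not of the generator.

Determinism: each run draws from an independent child stream of
`(seed, crc32(subject_id), run_index)`, so identical specs give
bit-identical output and runs are mutually independent.

**What the generator does not emulate**: volume conduction from a
biophysical head model, eye/muscle artifacts with realistic
spatio-spectral signatures, non-stationary background (drowsiness,
impedance drift), or inter-subject variability. Passing tests therefore
demonstrate that the pipeline's machinery is correct and calibrated —
not that real-data accuracy levels will be reached.

## Preprocessing

* Order: z-score → common average reference → notch cascade, following
  the acquisition narrative; z-scoring before CAR was an open choice and
  is configurable in code by composing the functions directly.
* All filters are applied zero-phase (forward–backward), which squares
  the magnitude response — acceptable offline, and it removes phase
  distortion. The notch is a Butterworth band-stop of design order 4
  with ±1 Hz stop band per notch frequency (no bandwidth was prescribed;
  ±1 Hz comfortably exceeds 40 dB attenuation at the line frequency
  while leaving a 10 Hz probe under 1 dB).
* Artifact statistic: channels are z-scored against their own run-wide
  mean/SD (computed on the normalized signal), the run is cut into
  non-overlapping 1 s segments, and a segment is flagged when its peak
  |z| exceeds 6. "Segment" length was an open choice; 1 s is stated and
  fixed. A run is rejected when more than 10% of channels have at least
  one flagged segment.
* Epochs use 0-based half-open intervals [onset, onset + duration); a
  3000-sample trial yields exactly ⌊(3000 − 600)/300⌋ + 1 = 9 windows.
* The 30 s baseline is generated but excluded from epochs; no stated use
  exists for it, and all decoding operates on task windows.

## FBCSP

* Per-window channel covariances are trace-normalized before averaging
  (scale invariance), and a ridge of 1e-6 × mean diagonal is added for
  conditioning.
* The generalized eigenproblem is solved by symmetric whitening of
  C₁ + C₂ followed by an ordinary eigendecomposition of the whitened C₁;
  filters satisfy wᵀ(C₁ + C₂)w = 1 and generalized eigenvalues lie in
  (0, 1). Sign convention: the largest-magnitude coefficient of each
  filter is made positive. Component order is frozen as [6 largest λ,
  6 smallest λ] because the downstream CNN is not permutation-invariant.
  Patterns (for topography export) are the pseudo-inverse of the
  selected filter matrix.
* Default pipeline order is one broadband CSP followed by the rhythm
  filter bank on the 12 component traces; `band_first=True` gives the
  classic per-band variant (one CSP per rhythm). The broadband order
  matches a single topography per component and is the default.
* Log power uses the per-window centered mean square with an ε = 1e-12
  floor; the centering mean is per window (per-run centering was the
  alternative; per-window keeps windows exchangeable units).
* The feature map is treated as a 1-channel 12 × 6 image per window,
  i.e. time is collapsed within each window before the CNN; a
  time-resolved input variant is out of scope.

## Network

* Implemented in NumPy (float64) with hand-written backward passes for
  every layer; correctness is asserted against central-difference
  numerical gradients in the test suite. Adam uses the standard
  bias-corrected moments.
* Both convolutions use "same" zero padding so the 12 × 6 plane is
  preserved — required for the (128, 12, 6) intermediate map.
* The spatial attention block produces a single 2D map via one 3 × 3
  convolution over the 2-channel [average; max] filter pooling (the
  standard CBAM construction). A described 32-filter spatial-attention
  convolution is irreconcilable with a single 2D attention map and was
  not implemented.
* The dense head is 64 units with ReLU (width unstated; 64 balances the
  576-dim flattened input against the small window counts), dropout 0.3,
  softmax output. Weight init is fan-in-scaled uniform from a recorded
  seed; dropout draws from a separate recorded stream and is disabled in
  evaluation, so eval-mode forwards are deterministic.
* Variants with no leading convolution (CBAM-only, CBAMs) apply filter
  attention to the single input map; the reduction ratio is forced to 1
  there so the MLP stays well-defined.
* Max-pool backward splits gradient equally among tied maxima (ties have
  measure zero on real-valued features).

## Training and voting

* Optimizer Adam at the stated learning rate 0.001 (the optimizer itself
  was unstated); loss is categorical cross-entropy; the final model is
  the last epoch's weights — validation curves are reported, not used
  for selection.
* Validation is carved per binary pair, trial-wise and stratified by
  class (10% of the pair's training trials), guaranteeing both classes
  appear in every validation set even at small scales. Trials never span
  partitions; shuffling affects only training batch order.
* Five-class prediction resolves each window through all 10 classifiers
  (one-vs-one), then majority-votes the 9 window labels per trial.
  Tie-breaking: sub-vote among the tied candidates, then largest
  cumulative softmax probability over each candidate's classifiers, then
  smallest label (the last step is a documented determinism guarantee).
* One master seed fans out through a seed sequence to the validation
  split, per-pair initialization/shuffling, and the permutation tests;
  reports serialize with sorted keys and are byte-identical across runs.

## Statistics

* Permutation test: predictions fixed, truth shuffled at trial level, no
  retraining (retraining 5000 times would be computationally
  inconsistent with the stated iteration count). The p-value is add-one
  smoothed, (1 + #{null ≥ observed})/(n_perm + 1); the raw proportion is
  also reported.
* Paired t-tests (scipy) are two-sided with stars at 0.05/0.01/0.001;
  zero-variance differences raise an undefined-statistic error rather
  than returning NaN.
* Bootstrap CI: percentile interval of 1000 resampled subject-mean
  accuracies.
* ROC: per binary classifier via threshold sweep (scikit-learn); no
  multiclass micro/macro averaging.
* Accuracy and κ are computed by their closed forms and cross-checked
  against scikit-learn from raw labels in the tests.

## Problem sizes used in tests

The test and acceptance suites run the full method at reduced scale so
the suite completes in a few minutes: grids of 3 × 3 to 6 × 6 electrodes
(same pitch and rate), 3–5 runs of 10–25 trials, 2–40 training epochs,
and networks of 8–32 first-layer filters. These sizes were chosen as the
smallest at which each property under test is informative: e.g. the
attention-vs-ablation comparison uses 4 training runs of 25 trials and
30 epochs, and null-calibration checks use 15–25 test trials where the
permutation band is still meaningfully narrower than [0, 1]. The
full-size configuration (256 channels, 10 runs, 128 filters, 150 epochs)
is the package default and runs through exactly the same code path.

## Known limitations

* No ICA/regression artifact correction or bad-channel interpolation;
  rejection is run-level only.
* The mutual-information band/feature selection of classic FBCSP is not
  implemented; all 12 × 6 features are passed to the classifier.
* Transformer and self-attention design variants are recognised
  identifiers but not implemented.
* The EDF loader for real recordings is not included; sessions enter as
  in-memory (Recording, EventTable) pairs or the HDF5 fixture format.
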