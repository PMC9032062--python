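# Methods

## Problem and scope

`rotordetect` detects *rotational activity* (rotors) — self-sustaining
re-entrant wavefronts — in multi-channel endocardial electrograms (EGMs)
recorded during atrial fibrillation with a 5-spline, 20-electrode star
catheter. It contains four scientific components:

1. a **rule-based staircase detector** over unipolar local activation
   times (LATs), usable both as a standalone detector and as the
   labeling oracle for classifier training;
2. a **synthetic EGM simulator** that generates annotated cohorts with
   planar, focal, fractionated and rotor activation patterns;
3. the **signal pipeline** (filtering, bipolar derivation,
   down-sampling, percentile normalization, windowing, augmentation,
   rebalancing, patient-wise splits);
4. three **binary window classifiers** — a dense baseline (SimpleCNN),
   a deep 1-D CNN with two LSTM layers (ATI-CNN style), and the
   convolutional-recurrent network (CRNN) — with a training and
   evaluation harness (accuracy, precision, recall, specificity, MCC,
   ROC/AUC, and a model × signal × length × rate experiment grid).

## Catheter model

Electrodes live on `n_splines` radial splines at evenly spaced angles,
`electrodes_per_spline` positions per spline at radii 2, 5, 8, 11 mm
(defaults; only the relative order matters to ring logic, the absolute
values only to the simulator's conduction geometry). Electrodes at the
same within-spline position form a concentric *ring*; ring order is
counterclockwise by increasing spline angle, and chirality labels are
defined relative to that orientation: LATs increasing along the ring
order = "counterclockwise". Adjacent within-spline electrode pairs give
15 bipolar channels for the default 5 × 4 layout.

## Rule-based staircase detector

* **LATs** are instants of maximum negative slope of each unipolar
  channel. Slope is the central-difference derivative in mV/ms; every
  local slope minimum below a threshold is a candidate, and candidates
  are accepted greedily by steepness subject to a refractory spacing.
  The default threshold is adaptive — 20% of the channel's
  98th-percentile absolute slope — and the default refractory is 90 ms.
  Both are artifact choices (exposed as parameters): 90 ms sits safely
  below the shortest simulated cycle length (100 ms floor), so
  consecutive beats at the fastest rates are never merged.
* **Dominant cycle length (CL)** is the pooled median of consecutive
  inter-LAT intervals over all channels; the median is robust to the
  occasional missed detection.
* **Ring staircase scan**: every LAT of every ring electrode anchors a
  frame of one CL. A frame is one candidate rotation when (a) each ring
  electrode has exactly one LAT inside it, (b) the LATs ordered by ring
  angle are cyclically strictly monotone (exactly one descent in the
  cyclic difference sequence — ascending = counterclockwise, descending
  = clockwise), and (c) their span exceeds 50% of the CL. Passing
  frames are thinned to one candidate per rotation (minimum start
  separation 0.7 CL). Anchoring on *all* electrodes rather than only
  the globally first-activated one makes the scan invariant to the
  rotor's phase at onset; for a periodic staircase every in-episode
  anchor selects the same rotation up to a cyclic relabeling, so the
  thinning step is well defined.
* **Events**: runs of ≥ 3 consecutive same-chirality candidates (gap
  between consecutive frames at most one CL) become rotational events
  with `n_rotations` = run length ("more than 2 consecutive events"
  read literally as ≥ 3; the threshold is a parameter). Overlapping
  same-chirality events from different rings merge into one, keeping
  the maximal rotation count.

Geometry guarantees the negative classes are rejected: a planar wave at
0.5 mm/ms crosses the 22 mm catheter in ≤ 44 ms, below the > 50 ms span
needed even at the 100 ms CL floor, and a sampled cosine over 5 equally
spaced angles always has at least two cyclic descents, so planar frames
also fail monotonicity. Focal spread gives near-equal ring LATs (ties →
rejected), and fractionated bursts scatter LATs uniformly, so a
same-chirality run of three monotone frames is vanishingly unlikely.

## Synthetic EGM simulator

The simulator is a statistical emulator, not a biophysical model. Each
acquisition (default 30 s at 1 kHz) draws one cycle length from a
truncated normal — mean 166.8 ms, SD 36.1 ms, floor 100 ms, the rotor
cycle statistics of persistent-AF cohorts mapped with this catheter —
and fills the timeline with background segments (planar wavefronts with
random direction 50%, focal sources 25%, fractionated activity 25%),
optionally interrupted by rotor episodes (probability `rotor_fraction`
per acquisition, 1–2 episodes of 3–8 rotations). During rotation *k*
of a rotor, the electrode on the spline at angle θ activates at
`t0 + (k + θ/360)·CL` (sign of the progression set by chirality), so
every ring sees a staircase spanning 4/5 of the cycle — the single-core
choice applies the same phase to all four rings. Segments are separated
by 180 ms guard gaps and every schedule is validated against a
refractory floor.

Each activation renders as a biphasic deflection
`s(u) = -A·√e·(u/σ)·exp(-u²/2σ²)` (σ = width/4, default width 8 ms,
amplitude 1 mV ± 20% jitter): its analytic derivative minimum falls
exactly at the scheduled LAT, which makes the maximum-negative-slope
convention exact by construction. Fractionated activity renders as
bursts of 3–5 deflections of 0.2–0.5 mV within 40 ms — the classic
false-positive surrogate for rotational activity. Optional common-mode
far-field deflections (0.2 mV, 30 ms wide, period drawn in 700–900 ms)
cancel exactly in bipolar derivation; optional 50 Hz mains and white
noise (default SD 0.05 mV) complete the model. Amplitudes are
configurable placeholders — no published amplitude statistics exist for
this data. All randomness flows from one seed.

What the simulator does **not** model: wavefront curvature and meander,
spatially varying conduction, electrode contact artifacts, amplitude
heterogeneity across the atrium, and rotors visible on only part of
the catheter. Tests passing on this generator therefore demonstrate
the pipeline's correctness and the architectures' capacity to learn
staircase structure, not clinical-grade performance.

## Signal pipeline

Filters are 4th-order Butterworth applied forward-backward (zero
phase), 30–240 Hz for bipolar and 0.1–100 Hz for unipolar channels,
plus an IIR 50 Hz notch; zero-phase filtering preserves LAT timing.
Down-sampling uses a polyphase anti-aliasing resampler with the sample
count contract `floor(n·target_fs/fs)`; binary LAT trains are re-binned
(max-pooled over decimation groups) instead of filtered. Windows are
normalized jointly over all entries: 2nd percentile → 0, 98th → 1,
clipped — per-window scope matches the training unit of computation; a
degenerate window (p98 = p2) maps to 0.5. LAT-train windows skip
normalization (they are already 0/1, and sparse binary percentiles
would degenerate).

Windowing uses 50% overlap (counts: 23 windows of 2500 ms or 119 of
500 ms per 30 s acquisition). A window is labeled positive when some
event overlaps it by at least one full rotation (the overlap rule is a
package choice — exposed with an "any-overlap" alternative — since
mapping 30 s annotations to sub-windows admits several conventions).
Rebalancing keeps all positives and a seeded 1:1 negative sample per
patient, dropping patients without positives. The patient split is
chronological (first 90% to training); validation is a stratified
window-level carve-out (12% default) from training patients, so test
patients stay disjoint. Augmentation applies the 5 spline rotations to
every partition (they are exact symmetries of the catheter) and
optional time/channel flips to training only.

## Classifier architectures

All models output one sigmoid unit; inputs are (time × channels)
normalized windows.

* **SimpleCNN** (dense baseline, the name is historical): flatten,
  dense 128 → 64 → 1 with rectifier activations.
* **ATI-CNN style**: 13 convolution layers of kernel 3 along time
  (electrodes enter as input channels) in five blocks of (2,2,3,3,3)
  layers with channels (64,128,256,256,256), max-pool 2/2 after each
  block, then two 32-unit LSTM layers. The published description of
  this family names only the convolutional and LSTM stages, so no
  attention mechanism is implemented; block arrangement and LSTM width
  are package choices.
* **CRNN**: symmetric 37-sample zero padding on the time axis, input
  batch-normalization and dropout, then three blocks of
  [conv (23 × 5 kernel, size-preserving) → batch-norm → leaky ReLU
  (slope 0.3) → max-pool → dropout 0.3] with 32/64/64 filters and
  boundary-truncating pools 2×2 (stride 2,1), 3×3 (stride 3), 4×4
  (stride 4), then two GRU layers of 32 units (first returns the full
  sequence) and the sigmoid unit. For a 1250 × 20 input the chain is
  1324×20 → 662×19 → 220×6 → 55×1 with 64 features entering the
  recurrence; for 15 bipoles the electrode axis runs 15 → 14 → 4 → 1.
  The kernel's long side (23) lies along the time axis — rectangular
  kernels exist to capture longer temporal context — with the flipped
  orientation available via a flag (the shape chain is identical either
  way because the convolutions preserve size).

### Numerical engine

No deep-learning framework is used: layers, Adam, and
binary cross-entropy are implemented directly on numpy (float32).
Convolutions are evaluated in the frequency domain — real FFTs over the
two spatial axes and per-frequency-bin channel-mixing matrix products —
which for these large activation maps and 23 × 5 kernels is an order of
magnitude cheaper than im2col matrix products; transforms of the padded
extent suffice because circular wrap-around only contaminates lags
outside the retained output range. The input gradient is the full
convolution with the spatially flipped, channel-transposed kernel, and
the weight gradient a correlation of the padded input with the output
gradient, both in the same FFT grid. Every layer's analytic gradient
is verified against central finite differences at float64 in the test
suite; forward convolution is additionally checked against
`scipy.signal.correlate`. Max-pooling is separable (time then
electrode axis) with boundary truncation (`floor((n-k)/s)+1`);
tie-breaking takes the first maximum, a valid subgradient.

### Training

Adam (β₁ 0.9, β₂ 0.999, ε 1e-7), binary cross-entropy on logits, batch
size 32, learning-rate grid {1e-2, 1e-3, 1e-4}, early stopping on
validation accuracy with best-weight restoration. Epoch budget and
patience are package choices (default 50 epochs, patience 10 at small
scale). Initialization is Glorot-uniform from the model seed; dropout
noise is seeded independently so identical seeds give identical runs.

## Evaluation

Accuracy, precision, recall, specificity and MCC follow the standard
confusion-matrix formulas; MCC's zero-denominator convention is 0 (the
value conventionally printed for degenerate one-class predictors), and
undefined ratios report 0 with a degeneracy flag. The decision
threshold for confusion-based metrics is 0.5. ROC curves sweep all
unique score thresholds; AUC is the trapezoid integral and equals the
Mann–Whitney rank statistic with ties counted one half (asserted
against exhaustive pair counting and scikit-learn in tests). The
experiment grid trains one model per (model, signal type, window
length, sampling rate) cell with per-cell seeds; infeasible cells are
marked failed and the sweep continues.

## Problem sizes used by the checks

The test suite verifies detector recovery on a noiseless 100-
acquisition cohort (sensitivity and per-acquisition specificity both
reach 1.0 at the default parameters) and end-to-end learnability on a
14-patient synthetic cohort yielding ≈ 2,100 balanced, augmented
bipolar training windows of 2500 ms at 500 Hz; the CRNN trains for two
capped epochs (about 100 batches) at learning rate 1e-2 — the grid
member that converges fastest at this scale — with validation-based
best-weight selection, and is compared against the dense baseline on
held-out patients. These sizes are the package's chosen demonstration
scale for a laptop-class CPU; larger cohorts and the full
learning-rate grid use the same code paths.

## Known limitations

* The simulator's rotors are perfectly periodic and catheter-centred;
  real rotors meander, drift, and partially overlap the catheter.
* The rule detector's dominant cycle is estimated over the whole
  acquisition, which assumes a reasonably stationary cycle length.
* The ATI-CNN reconstruction is under-determined by its published
  description; it serves as a comparator family, not a faithful
  replica.
* Training at the full 2500 ms × 500 Hz scale on CPU is slow (~10 s
  per batch of 32); GPU-scale sweeps are out of scope.
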