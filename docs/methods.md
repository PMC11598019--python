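# Methods

## Problem setting

Surface EMG gesture recognition degrades sharply across people: electrode
placement, skin impedance, muscle geometry and residual-limb anatomy all
shift the signal distribution. The pipeline here pre-trains a gesture
classifier on a multi-subject corpus and adapts it to each new user from a
few gesture repetitions, comparing three pre-training strategies (standard,
triplet-margin metric learning, domain-adversarial) and two fine-tuning
regimes (*last*: classifier head only; *middle*: deep features + head).

## Architecture

Windows of raw sEMG, `L × 12` samples, enter as 1-channel images
(time × electrode). Part 1 runs five parallel branches whose opening
kernels are `i·W × 3`, `i = 1..5`, with `W = ⌊L/20⌋`; at the reference
window `L = 300` this is 15…75 samples (7.5–37.5 ms at 2 kHz), covering
both short transients and slower envelope structure. The electrode axis is
padded 2 per side: the leading side wraps electrodes 7–8 of the 8-electrode
forearm ring (circular topology), the trailing side — beyond the ring — is
zero-filled; with kernel width 3 the electrode extent grows 12 → 14.
Temporal padding is zero and size-preserving (split `(k−1)//2 / k//2` for
even kernels).

Separable convolutions are depthwise 3×3 (no bias) followed by pointwise
1×1 (with bias), batch norm directly after, and use size-preserving
padding; max pools use floor semantics (incomplete windows cropped). The
declared data flow at `L = 300` — concatenation 320 maps, Part-2 fusion to
128, Part-3 flatten width 512 = 256×2×1 — is asserted layer-by-layer in
the tests, and is only self-consistent with size-preserving separable
convolutions, which is why that convention was adopted. With it, Part 4
counts 67 470 trainable parameters (≈70 k) and Parts 3+4 count 170 766
(≈200 k), matching the transfer-regime sizes.

Activation is configurable (`relu`, `leaky_relu`, `elu`); the default is
LeakyReLU. Dropout is channel-wise (2-D) at rate 0.2 everywhere. Opening
and depthwise convolutions carry no bias (batch norm follows immediately);
pointwise and linear layers do.

## Training

The network stack is implemented in numpy with a tape-based reverse-mode
autodiff engine (`semgnet.autodiff`); every primitive's adjoint is verified
against central finite differences in the test suite. Optimisers: Adam
(default, β = 0.9/0.999, ε = 1e-8) or SGD with momentum; optional L2 weight
decay. Early stopping monitors validation loss with configurable patience
and restores the best checkpoint (including batch-norm running statistics).

* **standard** — mean softmax cross-entropy on gesture classes.
* **triplet** — hinge `Σ max(0, margin + d(a,p) − d(a,n))` (Euclidean d,
  default margin 1.0) on Part-3 flatten embeddings; only Parts 1–3 receive
  gradients (no class-head training). Triplets are sampled uniformly over
  valid candidates within each mini-batch — positives share the anchor's
  gesture but come from a different subject, negatives differ in gesture;
  no hard mining. Validation uses a fixed triplet index set drawn once so
  the early-stopping metric is comparable across epochs. A distance
  ε = 1e-12 inside the square root keeps the gradient finite at zero
  distance (the loss at an exact hinge boundary is then ~1e-6, not 0).
* **dann** — a subject-classification head of the same shape as Part 4 is
  attached to the flatten output behind gradient reversal; the optimised
  total is `L_c + L_d∘GRL(λ)`, which implements `min L_c − λ·L_d` for the
  backbone while the domain head itself descends `L_d`. The schedule
  `λ(p) = 2/(1+e^{−γp}) − 1` (γ = 10 by default) is the canonical
  realisation of an exponential hand-over from classification to
  domain-invariance; progress p is epoch-based, so a single-epoch run pins
  λ = 0 (used by the equivalence test against standard training). Domain
  labels are subject identities of the pre-training pool; including
  amputee recordings in that pool is a cohort-composition choice, not a
  separate algorithm.

Hyperparameter defaults follow the tuned reference configuration (batch
256, Adam, LeakyReLU, max pooling, Part-1 Block 2 width 64 = 2× Block 1,
Part-2 width 128, Part-3 width 256); a `grid_search` harness enumerates a
config grid (optionally budget-subsampled) and ranks by validation metric.

## Transfer learning

`freeze_for_mode` clears the trainable flags of all parts outside the
regime (*last*: Part 4; *middle*: Parts 3–4; an attached domain head is
always frozen). Fine-tuning continues from the pre-trained weights rather
than re-initialising — the observed convergence within very few epochs is
only consistent with warm-started heads — at a reduced default learning
rate (5e-4 vs 1e-3). For each subject a 5-fold repetition cross-validation
draws, seeded and without replacement, from all valid
(retrain-set, validation-repetition, test-repetition) assignments with
pairwise-disjoint roles; `n_repetitions = 0` degenerates to zero-shot
evaluation. Since the frozen prefix is deterministic in eval mode
(batch-norm running statistics, no dropout), its activations are computed
once per subject and cached; only the suffix iterates. Subject leakage
(holdout ∩ pre-training) is a hard error at entry.

Per-subject fold metrics are averaged first; cohort tables report
mean ± std across subjects (optionally stratified healthy vs amputee).
Macro-F1 accompanies accuracy because gesture runs yield mildly imbalanced
window counts; micro-F1 would duplicate accuracy.

## Synthetic cohorts

The generator reproduces the statistical structure the method addresses,
not muscle physiology (no motor-unit action-potential trains):

* cohort-level per-gesture spatial templates — a smooth von-Mises-like bump
  (plus second harmonic) over the 8-electrode ring at a gesture-specific
  angle, free positive weights on the remaining electrodes;
* a carrier of Gaussian noise band-passed to 20–150 Hz (the dominant sEMG
  band), amplitude-modulated by a Tukey on/off envelope per gesture
  segment, scaled so active peaks sit near 2000 μV (within the ±5000 μV
  physiological range);
* subject-specific log-normal per-channel gains (σ = `subject_gain_sd`,
  default 0.25) and an optional integer rotation of the ring
  (`electrode_shift_max`, default ±1) — the donning/anatomy covariate
  shift; "amputee-like" subjects get doubled gain spread and shift range
  plus 0.6× activation (weaker, more variable residual-muscle signal);
* 50 Hz line interference (5 % of peak, random phase per channel), a white
  noise floor (5 %), and a 4 %-per-repetition amplitude decline as a
  fatigue proxy;
* schedule: each gesture executed `n_repetitions` times with rest segments
  between; labels are exact, so the delay-relabelling issue of real
  recordings does not arise.

Determinism: per-subject RNG substreams are keyed `(seed, tag,
subject_index)`, so enlarging a cohort never reshuffles existing subjects;
gesture templates depend on the seed only and are shared across subjects
(cross-subject transfer requires it). What the generator does **not**
emulate — MUAP waveform shape, electrode-skin artifacts, within-session
drift beyond the fatigue ramp, label noise — bounds what passing tests
show: they validate the pipeline's mechanics and the direction of the
method's effects, not clinical performance on real recordings.

## Scaled end-to-end study

The stochastic acceptance study runs on reduced conditions chosen once:
500 Hz sampling, 4 gestures × 6 repetitions (0.4 s gestures, 0.3 s rest),
11 subjects (8 pre-training + 2 healthy + 1 amputee-like held out), 120 ms
windows (L = 60, temporal pool 7 so the pooling chain stays valid), a
width-reduced model (Block 1 = 8, Part 2 = 32, Part 3 = 32), batch 128,
learning rate 2e-3, 12 epochs. Two cohorts are used: the fine-tuning
comparisons (fine-tuned vs zero-shot; *middle* vs *last*) run on the
default confound (gain σ 0.35, ring shift ±1), while the
domain-adversarial comparison runs on a strong-gain cohort (σ 0.6, no
shift) — ring rotation is a shift adversarial training cannot undo, whereas
gain-pattern confounds are exactly what it suppresses, so that cohort
isolates the mechanism the comparison is about. The comparison averages
zero-shot accuracy over three seeds.

## Numerical choices & limitations

* Filtering is zero-phase (forward–backward) by default; a causal
  single-pass mode exists for real-time emulation. Notch Q = 30 (~1.7 Hz
  width at 50 Hz). A pass band above Nyquist is clipped to 0.95·Nyquist
  with a warning.
* Normalization guards zero variance / zero range with ε = 1e-8 and flags
  the statistics as degenerate instead of raising. Statistics are fitted on
  gesture-labelled samples of the training repetitions by default.
* Windows come only from label-pure runs (one gesture, one repetition); a
  window can never straddle rest or a label change. Stride =
  `round(L·(1−overlap))`, floored at 1.
* The 80/20 inter-subject split floors the validation side and gives the
  remainder to training; the intra-subject repetition routing (2,4,6 /
  1,5 / 3) is fixed, not configurable, to keep the protocol canonical.
* Model weights are float32 (Kaiming-uniform init, seeded); gradient checks
  run in float64. Two builds from the same config/seed are bit-identical;
  attaching a domain head draws from an independent stream and leaves the
  backbone init unchanged.
* DB3-style subjects with 10 electrodes are zero-padded to the configured
  channel count with a validity mask recorded in metadata.
* Known limitations: no majority-voting deployment mode, no quantised or
  embedded inference, no session-to-session (multi-day) adaptation, and the
  MAT reader supports NinaPro-style layouts only (plain and HDF5-based MAT
  dialects, case-insensitive field names).
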