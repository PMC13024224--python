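# Methods

## Problem and model

The package addresses screening-style classification of short
frontal-view walking videos into Normal, Genu varum (bow-legged) and
Genu valgum (knock-kneed) leg alignment, with a binary Normal/Abnormal
view obtained by merging the two malalignments.  Labeled clinical video
is scarce, so the classifier is trained semi-supervised.

The classifier is a 3-D residual convolutional network: a stack of
two-convolution residual blocks over a `(B, C, T, H, W)` clip tensor.
Its terminal global pooling is replaced by a **spatial hierarchical
pooling module (SHPM)**.  For each pyramid level with block size
`(H_size, W_size)` the final feature map is partitioned into
`H_bins x W_bins = (H/H_size) x (W/W_size)` non-overlapping blocks, and
each block contributes its maximum

    mu[b,c,t,i,j] = max_{h,w} X[b,c,t, i*H_size+h, j*W_size+w]

and its mean `eta[b,c,t,i,j]` over the same indices.  Per-frame
statistics are averaged over the temporal axis and all levels are
concatenated into one feature vector feeding a single linear
classification layer.  Divisibility of every level is checked when the
network is built, never silently padded.

Training follows the **Mean Teacher** scheme.  The student is trained by
backpropagation; the teacher's parameters are an exponential moving
average `theta' <- alpha*theta' + (1-alpha)*theta` (alpha = 0.99),
updated after every optimization step, initialized at `theta' <- theta`,
and never receiving gradients.  Normalization running statistics are
EMA-tracked exactly like weights, so the teacher is a self-consistent
network at all times.  Per step the loss is

    total = L_sup + lambda(epoch) * (J + L_pseudo)

* `L_sup`: cross-entropy on labeled clips (student sees a strongly
  augmented view).
* `J = E ||p_student - p_teacher||^2_2`: squared 2-norm consistency
  between softmax outputs on unlabeled clips; the teacher consumes a
  weakly augmented view of the same clip, the student a strongly
  augmented one.  Soft targets deliberately preserve teacher
  uncertainty.
* `L_pseudo`: cross-entropy against confidence-gated *hard* teacher
  labels (max probability strictly above tau = 0.8) on the same
  unlabeled batch.
* `lambda(epoch)` ramps linearly from 0 to 1.0 over the first 30 epochs
  (configurable), so supervised structure is established first.

One printed form of this objective weights the supervised term by
`lambda` and the consistency term by `1 - lambda`; that would anneal
supervision away entirely as the ramp completes, contradicting both the
accompanying training protocol ("the consistency weight increases from 0
to 1.0") and the standard Mean Teacher formulation, so this
implementation keeps the supervised term at weight 1.  The divergence is
deliberate and this is the only place it is documented.

After each epoch in the semi-supervised phase the teacher scores the
remaining unlabeled pool; samples whose confidence strictly exceeds tau
are *promoted* — they leave the pool and join the supervising set with
their hard pseudo-label, flagged `pseudo` so a ground-truth label can
never be overwritten.  The loop terminates when the pool is empty or a
full pass promotes nothing.

Optimization is Adam (lr 1e-4, betas 0.9/0.999 at full scale; lr 1e-3
for the desk-scale preset below), batch 16 (8 at desk scale), up to 100
epochs with early stopping after 10 stagnant validation epochs and
learning-rate halving after 5 (monitored quantity: validation loss).
The split is at subject level, 64/16/20 train/validation/test, rounded
half-away-from-zero for validation and test with the remainder to train;
no subject appears in more than one split, and evaluation asserts this.

## Implementation note

The network, its backward passes and Adam are implemented directly in
NumPy (`gaitssl.nn`): 3-D convolution via im2col with the input gradient
computed as a gather-form transposed convolution, batch normalization
with full train-mode backward, and an SHPM layer whose max-pooling
gradient routes to the per-block argmax.  All gradients are verified
against central finite differences in float64 in the test suite.
Softmax is computed shift-invariantly; cross-entropy clamps
probabilities at 1e-12.

## Synthetic data

Real pediatric gait video cannot be redistributed, so the package ships
a generator of frontal-view articulated stick walkers whose class is
determined by the same frontal-plane geometry clinicians use: the knees'
horizontal displacement off the straight hip-ankle line, in
fraction-of-leg-length units (`knee_offset`).  Negative values push the
knees outward (varum: inter-knee distance exceeds inter-ankle distance
at mid-stance); positive values pull them inward (valgum); the class
boundary margin is 0.05.  Class-conditional sampling bands
(normal within +-0.02, |offset| in 0.15-0.30 for the deformities) keep a
clear gap to the boundary, so the desk-scale task is well-posed: a
trivial geometric classifier recovers every noise-free label, which the
tests assert.

Nuisance variation per subject: stride period 8-24 frames, walker height
0.5-0.9 of the frame, additive Gaussian pixel noise with sd up to 0.05,
and a uniform initial gait phase.  Legs swing in antiphase with one lift
per cycle; a small trunk bob is added.  Rendering uses anti-aliased line
segments with joint disks, grayscale in [0, 1], optionally tiled to 3
channels.  What the generator does **not** emulate: photorealistic
appearance, clothing, occlusion, background clutter, camera pose or
viewpoint changes, multi-person scenes, or the other gait abnormalities
(foot dragging, trunk sway).  Passing the desk-scale experiments
therefore demonstrates that the learning machinery works end to end on
geometry-defined classes — not clinical-grade performance on real
children.

## Desk-scale experiment protocol

All reference experiments (`gaitssl.experiments`) use 60 subjects,
balanced classes, one 8-frame 32x32 clip per subject, the `tiny`
backbone preset (2 stages x 1 block, channels 8/16, final map 8x8 so the
dyadic SHPM pyramid 1x1/2x2/4x4 is nontrivial), subject-level 64/16/20
split, batch 8 and learning rate 1e-3.  These sizes were chosen so a
single CPU core runs each experiment in seconds to minutes.

* **Learnability**: fully supervised, 30 epochs, 5 seeds; test accuracy
  is expected at or above 0.9 for most seeds.
* **Semi-supervised comparison**: 20% of *training* subjects keep
  labels, the rest form the unlabeled pool; validation and test stay
  labeled.  15 epochs with the consistency ramp shortened to 10 epochs
  so the weight reaches its ceiling within the run.  Arms: full Mean
  Teacher, supervised-only ablation (unlabeled pool dropped) and a
  global-average-pooling ablation (SHPM removed); reported as
  mean +- sd and medians over 5 seeds.
* **Saliency localization**: Grad-CAM with the last convolutional block
  as target layer — channel weights are the spatiotemporal mean of the
  class-logit gradient, the map is the rectified weighted activation
  sum, trilinearly upsampled and min-max normalized per clip.  The
  fixture blanks the upper half of every frame *and* restricts the
  trained classifier to lower-half SHPM bins, so the logits provably
  depend only on the lower half; the experiment then measures how often
  the Grad-CAM mass concentrates there.

## Numerical and design choices

* Crop windows are 0-based and half-open; the center-crop offset is
  `floor((dim - crop)/2)`.
* Clip windows default to non-overlapping (stride = clip length); a
  shorter tail is dropped.  All clips inherit the video-level label and
  video-level predictions are the mean of clip softmax vectors.
* Binary decisions threshold the Abnormal probability (varum + valgum
  mass) at 0.5 with ties resolved toward Normal; the pseudo-label
  threshold 0.8 is a training-time device only.
* Macro F1 is the harmonic mean of macro precision and macro recall —
  not the mean of per-class F1 scores; the two differ and the tests
  include a matrix where they do.
* Zero-denominator metrics are NaN with a warning, never silent zeros.
* PR-AUC uses step interpolation (the average-precision sum) with tied
  scores grouped at one threshold; it is cross-checked against an
  independent library implementation in the tests.
* Weak augmentation: translation up to 1 px (desk scale) and horizontal
  flip at p = 0.5.  Strong augmentation composes, in fixed order: speed
  perturbation (factor 0.8-1.25, nearest-frame resampling), temporal
  jitter (+-2 frames), translation up to 3 px, flip, brightness and
  contrast jitter (+-20%), Gaussian noise (sd 0.03), random erasing.
  Degenerate magnitudes reduce every transform to the identity.  Test
  time applies the center crop only.
* Initialization is He fan-out for convolutions, zero classifier bias,
  all seed-controlled; one integer seed fans out to independent streams
  for initialization, batch order and each augmentation branch.

## Known limitations

* Classic Grad-CAM weights channels globally, so activations in
  signal-free regions (e.g. a blank half of the frame, which batch
  normalization maps to a constant positive response) can receive
  nonzero saliency; for classes whose evidence is geometric suppression
  (valgum: knees approaching each other) the unrestricted trained model
  occasionally spreads mass above the legs.  The localization fixture
  removes this ambiguity by construction; see above.
* The tiny preset preserves the temporal axis (no temporal striding);
  deeper presets halve it per stage.
* Checkpoints are Python pickles of config + arrays and are not
  portable across incompatible package versions (a version field is
  checked).
* Training on full-scale 16-frame 224x224 clips with the ResNet-18
  preset is supported by the same code paths but is not practical on a
  single CPU; the desk-scale preset is the tested configuration.
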