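# Methods

## Overview

`ttcnet` implements a deep multi-task convolutional model for joint
classification and regression on 2-D grayscale images, together with the
preprocessing pipeline it is designed around: Canny edge detection,
edge-density landmark detection, and fixed-size patch extraction.  The
intended application is diagnostic imaging at desk scale — predicting a
categorical disease label and a continuous disease measure (here, lesion
area as a 2-D proxy for tumor volume) from the same input — but nothing
in the library is specific to brain images.

## The multi-task model

Each task `p` (a classification or a regression head) owns a *subnet*
`f(A, W^p)` of identical architecture: a stack of conv blocks
(3×3 convolution, stride 1, same padding → batch normalization → ReLU or
LeakyReLU → 2×2 max pooling), a hidden dense layer, and a task head
(softmax for multi-class, sigmoid for binary, linear for regression).
Per-task costs are the batch-mean binary/categorical cross-entropy
`D = −[B ln F + (1 − B) ln(1 − F)]` (probabilities clamped to
`[1e−7, 1 − 1e−7]` before the logs) or mean squared error.

Tasks are coupled during training by *task-transfer connections* (TTC):
a gate matrix `alpha` with `alpha[p][q] = sigmoid(beta[p][q])` for
`p ≠ q` and `alpha[p][p] ≡ 1`.  One training step consumes one batch per
task and performs:

1. per-task gradients `g_q = ∂D_q/∂W^q` at the current weights, clipped
   to global L2 norm 5.0;
2. cross-task velocities `V^{W^{pq}}`: `g_q` mapped tensor-by-tensor
   onto subnet `p` (the identity correspondence between congruent
   tensors; heads of differing width receive zero), converted to a
   velocity by the optimizer rule (plain SGD `V = −η g`, or momentum
   `V_{t+1} = μ V_t − η g`);
3. weight updates `W^p ← W^p + Σ_q alpha[p][q] · V^{W^{pq}}`;
4. gate updates for unfrozen off-diagonal pairs:
   `beta[p][q] ← beta[p][q] − η_β · s · alpha(1 − alpha)` with the
   first-order alignment surrogate `s = ⟨g_p, V^{W^{pq}}⟩`.

The surrogate is exactly the first-order change of the *receiving*
task's cost along the incoming velocity, so gates open between tasks
whose supervisory signals help each other and close between conflicting
tasks.  Two degenerate limits hold bit-exactly and are asserted in the
test suite: with all off-diagonal gates at 0 the model decomposes into
independent single-task learners, and with identical subnets, shared
batches and uniform gates all subnets receive identical updates.

The diagonal gate is pinned to exactly 1 (a sigmoid cannot reach 1), so
each task's own signal always dominates.  Batch-norm statistics are
per-subnet and never mixed across tasks.  Inference for task `p` uses
only `W^p` (running batch-norm statistics); the cross-task influence is
embedded in the training history, not in the forward pass.  An
activation-level coupling (cross-stitch style) is deliberately not
implemented.

### Parameters that matter

| parameter | default | notes |
|---|---|---|
| learning rate `η` | 1e-3 | validated range [1e-4, 1e-3] |
| gate learning rate `η_β` | 0.01 | scales with `η`: `s ∝ η⟨g_p, g_q⟩`, so small `η` needs larger `η_β` for visible gate motion |
| momentum `μ` | 0 | plain SGD is the default; the experiments below use 0.9 |
| batch size | 32 | validated set {16, 32, 64} |
| `beta` initialization | 0 (`alpha` = 0.5) | uninformative midpoint |
| gradient clip | 5.0 global L2 norm | keeps cross-task mixing stable |
| conv channels | (8, 16, 32) | input side must divide by `2^blocks` |
| batch-norm eps / momentum | 1e-5 / 0.1 | running stats used at inference |

All tensors are float64 and every random draw flows from one run seed
fanned out to named `numpy.random.SeedSequence` substreams (subnet
initialization, batch shuffling, phantom generation), so training
trajectories are bit-reproducible.

### Incremental task addition

`add_task` grows a trained model by one task.  All pre-existing subnets
(weights *and* batch-norm buffers) and all pre-existing gates are
frozen; gates from the new task into old subnets are pinned fully closed
(`beta = −inf`, gate exactly 0), so old-task behaviour is provably
unchanged — the test suite checks bit-identity of every old tensor.
Only the new subnet and its incoming gates `beta[new, q]` learn.  Old
tasks still receive forward/backward passes to supply supervisory
gradients, with batch-norm running statistics left untouched.

A caveat discovered while validating the gate semantics: gradient inner
products between *independently initialized* networks carry essentially
no task-relatedness signal, because hidden-unit permutation symmetry
decorrelates their parameter frames.  `add_task` therefore accepts
`warm_start_from=<task index>` to copy an existing subnet's congruent
tensors into the new branch before training.  With a warm start the
incoming gates reliably rank a duplicated task above an unrelated one;
with fresh initialization (the default, matching the usual "new branch
learns its own parameters" formulation) the gates drift near their 0.5
midpoint.  Whether old tasks' gates toward the new task should ever
unfreeze is left as an experiment: set `model.ttc.frozen[p, q] = False`
after the call.

## Preprocessing

The edge detector is the classical four-stage Canny pipeline with every
convention pinned down (they matter for exact oracle tests):

* Gaussian kernel radius `ceil(3σ)`, unit mass, reflect-padded
  convolution; default `σ = 1.4`.
* 3×3 Sobel gradients; magnitude `sqrt(gx² + gy²)`; orientation
  `atan2(gy, gx)` in degrees.
* Non-maximum suppression along the orientation quantized to
  {0°, 45°, 90°, 135°}; ties at the 22.5° bin boundaries go to the lower
  bin; a pixel survives when its magnitude is `≥` both directional
  neighbours (plateaus survive, so thinning is idempotent); neighbours
  outside the image count 0.
* Hysteresis with absolute thresholds on the suppressed magnitude
  (defaults low 0.1, high 0.2): STRONG `≥ high`,
  WEAK `low ≤ s < high`, NONE otherwise; the final map keeps STRONG
  pixels plus WEAK pixels transitively 8-connected to a STRONG pixel.
  A quantile-threshold variant exists but is off by default.

Landmarks are strict local maxima of the Gaussian-smoothed binary edge
map (the *edge density*), selected greedily in score order with a
minimum pairwise separation (default `patch_size / 2`) — a deliberately
simple, deterministic stand-in for a learned anatomical-landmark
detector; external landmark coordinates can be supplied instead.
Patches are half-open square windows `[c − size//2, c − size//2 + size)`
centred on landmarks, reflect-padded at borders so every landmark yields
a patch; coordinates are 0-based `(x, y) = (column, row)`.  Patches from
one source image always share a train/validation/test split so no
source leaks across splits.

## Synthetic phantoms

The generator emulates the *structure* of the two public brain-MRI
benchmarks this model family is usually evaluated on, at desk scale:
three lesion families in proportions 708 : 1426 : 930 (the three-class
set, 3,064 images at full scale) and a binary mode with tumor prevalence
155/253.  Images are 64×64 by default (512×512 supported); a smooth
Gaussian-blob background plus one lesion per image:

* class 0 "meningioma-like": smooth high-contrast ellipse near the
  periphery (semi-axes 7–11 px, contrast 0.35–0.50);
* class 1 "glioma-like": larger irregular region — a radially perturbed
  ellipse (semi-axes 9–14 px, boundary roughness 0.15–0.30, contrast
  0.20–0.30);
* class 2 "pituitary-like": small central round lesion (semi-axes
  5–7 px, contrast 0.25–0.40).

Additive Gaussian pixel noise (default sd 0.05) and clipping to [0, 1]
follow.  The regression target is the lesion-mask pixel count (px²);
the analytic boundary area `½∮R(θ)² dθ` (= `πab` for an unperturbed
ellipse) agrees with it to within ~2% discretization error at these
sizes.  A severity score (area × contrast) is emitted as an optional
third-task target.

What the phantoms do *not* emulate: MRI physics (bias fields, k-space
artifacts), anatomy, 3-D structure, multiple lesions, class-dependent
backgrounds.  Passing tests therefore demonstrate that the pipeline and
optimizer behave as specified on controllable statistical structure —
not that the model reaches any particular accuracy on real MRI data.

## Evaluation

Confusion-count metrics follow Eqs. accuracy `(TP+TN)/total`,
sensitivity (= recall) `TP/(TP+FN)`, F-measure = harmonic mean of
precision and recall.  Two specificity variants are exposed because a
definition that circulates in parts of the diagnostic-imaging
literature writes specificity as `TP/(TP+FP)` — algebraically
*precision*: `specificity(c, "paper")` reproduces that arithmetic,
`specificity(c, "standard")` is the conventional `TN/(TN+FP)` and is
the default everywhere.  Undefined metrics (zero denominators) are
reported as missing and excluded from means, never coerced to 0.
Multiclass problems are scored one-vs-rest and macro-averaged.

Splits are stratified 70/15/15 with globally controlled rounding (the
split sizes hit the largest-remainder targets exactly).  k-fold
cross-validation uses the conventional scheme — train on k−1 folds,
validate on the held-out one — with stratified folds whose sizes differ
by at most one.  (Some descriptions of 10-fold cross-validation invert
the phrasing, training on one fold and validating on nine; the
conventional scheme is used here.)  RMSE is reported in target units
and as a percentage of the observed target range, since "RMSE %" without
a stated denominator is ambiguous.

## Experiment scales and numerical choices

The bundled experiments (test suite and `scripts/acceptance.py`) run on
one CPU in minutes, at sizes chosen as the package's own desk-scale
defaults: 64×64 phantoms, 900 training / 300 test images for the joint
recovery experiment, 100–200 optimizer steps for the degeneracy and
gate-adaptation checks, small subnets (one conv block, 8-unit hidden
layer) for finite-difference gradient checks.  The joint experiment
uses momentum 0.9 and 20 epochs; plain SGD needs substantially more
epochs for the regression head at the validated learning-rate cap.

Training batches are augmented by the eight square symmetries (dihedral
flips and 90-degree rotations), drawn from the per-task batch stream, on
by default in the pipeline: both targets — class family and lesion
area — are invariant under these transforms, and without augmentation
the area-regression head overfits the 900-image training set (train
R^2 ~0.96 against test R^2 ~0.75; augmentation closes the gap to
~0.89 on both).

Degenerate inputs are handled explicitly: empty batches, empty landmark
lists, a class with fewer samples than splits (warns and falls back to
unstratified), non-finite costs during training (aborts and restores the
last end-of-epoch snapshot), zero-variance regression targets (unit
standardization).  Checkpoints round-trip bit-exactly (float64 `.npz`
plus a YAML descriptor).

## Known limitations

* Gradient mixing assumes congruent subnets in a shared parameter frame;
  across independently initialized subnets the gate-learning signal is
  weak (see the warm-start note above).
* Task heads of different width exchange no velocity at the head level;
  only the shared trunk is coupled.
* The landmark detector is intensity-driven plumbing, not a learned or
  anatomical detector.
* No GPU path; the numpy implementation targets desk-scale images
  (64–128 px) and minute-scale training runs.
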