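# Methods

This note records the modelling and numerical choices behind `cotresnet`,
what the synthetic data does and does not establish, and the points where
the design was genuinely open.

## Network blocks

### CoT block

The contextual-transformer block replaces a 3×3 convolution while keeping
input and output shapes identical. Its exact composition here is:

* static context `K¹`: k×k convolution (same padding) → batch norm → ReLU;
* value embedding `V`: 1×1 convolution → batch norm;
* attention embedding: the channel concatenation `[K¹, X]` (the query is the
  raw input) passes through 1×1 conv → batch norm → ReLU → 1×1 conv to
  `heads · k²` channels. The first 1×1 conv reduces `2C` channels by the
  factor `reduction` (default 4);
* the logits are softmax-normalised over the k² neighborhood of each
  position (per head), so the aggregation weights at every output position
  sum to 1;
* dynamic context `K²`: the attention-weighted sum of each position's k×k
  neighborhood of `V`;
* output `Y = K¹ + K²` — a plain elementwise sum, not a gated fusion. The
  simple sum is the fusion this package commits to; a learned gate would add
  parameters without changing any of the structural properties tested here.

Defaults: `kernel=3`, `reduction=4`, `heads=1`. Heads must divide the
channel count and `2C` must be divisible by the reduction; both are
validated at construction. The `K²` aggregation is local-window attention —
each output position attends over its own k×k neighborhood. Although such a
branch is often described as "global" context (the attention weights are
input-dependent, unlike a convolution's), its receptive field per layer is
exactly k×k; stacking blocks is what grows it.

### Residual block variants

* `basic_cot`: 3×3 conv (carries the stride and any width change) → BN →
  ReLU → CoT → BN, plus skip, final ReLU. The CoT replaces the *second*
  convolution of the basic block, keeping a strided convolution available.
* `ccs_bottleneck`: grouped 1×1 conv → BN → ReLU → channel shuffle → CoT →
  BN → ReLU → grouped 1×1 conv to 4×mid → BN, plus skip, final ReLU. Shuffle
  groups always equal the grouped-conv groups. The CoT cannot stride, so
  downsampling blocks put a 2×2 average pool (stride 2) in front of it and
  the shortcut uses a stride-2 1×1 projection.
* `bottleneck_shuffle_only`: as above with a plain 3×3 core (which strides
  itself); at `g=1` its parameterisation collapses exactly to the plain
  bottleneck, which is what makes the ablation chain airtight.
* `plain_basic`, `plain_bottleneck`: the unmodified baselines.

Every convolution followed by a norm carries no bias (the norm's shift
subsumes it); batch norm follows every convolution and precedes every
activation, the standard residual-network placement. Zeroing a branch's
final norm reduces any block to an activated (projected) identity — the
residual contract the tests enforce.

Group count `g` defaults to 4 and is configurable; it must divide every
grouped channel count, which the specs validate eagerly rather than at
forward time.

## Architectures

`cot_resnet18`/`resnet18` stack (2,2,2,2) basic blocks at widths
(64,128,256,512); `ccs_resnet50`/`resnet50`/`resnet50_shuffle` stack
(3,4,6,3) bottlenecks at the same mid widths with 4× expansion. The stem is
a 7×7 stride-2 convolution to the first stage width followed by 3×3 stride-2
max pooling; the head is global average pooling into a single fully
connected layer with `n_classes` outputs (2 for the pairwise tasks, 3 for
AD:MCI:HC) — there is no intermediate 1000-d layer, which belongs to
ImageNet-scale classification. Softmax is applied at inference
(`predict_proba`); training consumes logits directly for numerical
stability.

MRI slices are grayscale, so `in_channels` defaults to 1. Weights are
He-normal for convolutions, unit/zero for norms, seeded through one
generator per model so builds are reproducible.

A `width_multiplier` scales all stage widths. It exists purely so that the
full architectures can be exercised and trained at desk scale (1/8 is used
throughout the tests); it is not part of the reference configurations.

## Autodiff engine

No deep-learning framework is a dependency; the package carries a small
reverse-mode autodiff engine over numpy arrays (`cotresnet.autodiff`).
Convolution, pooling and the CoT aggregation are composed from one im2col
primitive (`unfold_nbhd`) plus batched matmul, so a finite-difference check
of the primitives (run in float64 in the test suite) validates the gradients
of every layer. Max pooling splits gradient equally among ties; softmax
subtracts a detached rowwise max for stability; the training loss uses
log-softmax rather than log(softmax).

## Preprocessing

* Min–max normalisation maps each volume affinely onto [0, 255]; a constant
  volume becomes all zeros with a warning (there is no range to map). The
  operation is idempotent.
* Resampling to 128³ is trilinear; linear kernels cannot overshoot the input
  range.
* Slice selection: "the clearest 20 coronal slices" is not an operational
  rule, so the package takes `n_slices` evenly spaced slices centred on the
  coronal midline, with a default spacing that makes the span cover the
  central ~30% of the coronal axis — the hippocampal region that motivates
  coronal slicing in the first place. Deterministic by construction.
* The coronal axis is read from NIfTI orientation metadata (the axis with an
  anterior/posterior code); if the affine carries no orientation, axis 1 is
  assumed with a warning.
* The 8:1:1 split shuffles *slices* and allocates floor(n/10) to validation
  and test with the remainder to train (10,060 → 8,048/1,006/1,006). Because
  slices are shuffled rather than subjects, slices of one subject can land
  in different partitions; this matches the common slice-level protocol but
  leaks subject identity across splits, so reported test metrics are
  optimistic relative to subject-level generalisation. `by_subject=True`
  provides the leakage-free alternative.
* Volumes arrive at 128³ while the canonical network input is 224²; when the
  two must be reconciled, slices are bilinearly resized at load time
  (`image_hw=(224, 224)` / `--input-size 224`). Networks are otherwise
  size-agnostic thanks to global average pooling, and the desk-scale runs
  feed native-resolution slices.

## Synthetic phantoms

Each phantom is an ellipsoidal bright "head" (tissue 1000 intensity units)
containing a central dark "ventricle" ellipsoid (100 units) whose nominal
radius grows with disease stage (HC/MCI/AD means 6/9/12 voxels at grid 128,
scaled proportionally at other grids), and a bright inferior half-shell
"hippocampal band" (1400 units) whose thickness shrinks with stage
(6/4.5/3 voxels), plus additive Gaussian noise (sd 30). Radius and
thickness are jittered per volume (sd 0.5 and 0.3 voxels) and the ventricle
centre receives a sub-voxel uniform offset (±0.5 voxel) so that voxelisation
error varies across volumes and cohort statistics behave like samples; with
noise and all jitters zero the volume is a deterministic function of its
label. All randomness flows through one explicit generator.

The defaults make AD-vs-HC strongly separable and MCI intermediate,
mirroring the relative difficulty of the clinical tasks. The phantoms
deliberately omit MRI physics — bias fields, Rician noise, partial-volume
effects, anatomical variability — so passing tests demonstrate that the
pipeline, architectures, gradients and schedule work as specified, **not**
that any accuracy level transfers to real MRI.

Morphology estimators (`estimate_ventricle_radius`, via the equivalent
ellipsoid volume of the thresholded dark region; `estimate_band_thickness`,
via the half-shell volume formula 2πR²t) let tests verify that generated
cohorts recover their configured class means within sampling error.

## Training schedule

Reference configuration (`TrainConfig` defaults): Adam (betas 0.9/0.999,
eps 1e-8) at lr 3e-5, batch size 32, up to 100 epochs; validation accuracy
is evaluated every epoch; the learning rate decays ×0.1 after 10 epochs
without a validation-accuracy improvement; training stops after 30 epochs
without a training-loss improvement; the parameters with the best validation
accuracy are restored on return. The plateau criterion tracks validation
*accuracy* (an epoch "improves" when accuracy strictly increases); the
early-stopping criterion tracks training loss. Cross-entropy clamps the true
class probability at 1e-12 so a confident wrong prediction yields a large
finite loss rather than an overflow.

Desk-scale runs — width-1/8 networks on a few hundred native-resolution
phantom slices — use lr 3e-4: the reference 3e-5 is sized for full-scale
training, and at desk scale it underfits purely for lack of update steps
(the loss still decreases monotonically, just slowly). Problem sizes used in
the tests and the acceptance script: phantom grids of 32 (cohort counting,
trainability of all five architectures on a 200-slice task) and 64 (the
separable AD:HC sanity task, 16 subjects × 10 slices); the full 503-subject
cohort is generated at grid 32, where the per-class slice counts are
identical to those at 128 by construction.

For binary tasks the positive class is the more-impaired one (AD in AD:MCI
and AD:HC; MCI in MCI:HC). The three-class task reports top-1 accuracy;
macro-averaged precision/recall are computed only on request. Precision or
recall with an empty denominator is reported as 0 with an `undefined` flag
rather than as NaN.

## Known limitations

* Pure-numpy execution is single-threaded apart from BLAS; full-width
  training at 224² is possible but not practical — the package is built for
  structural and desk-scale dynamical studies, not for reproducing
  full-cohort accuracy tables.
* Slice-level splitting leaks subject identity (see above); subject-level
  splitting is available but not the default, to match the standard
  protocol.
* The phantom generator's realism is intentionally minimal; it grounds
  correctness claims, not clinical ones.
* Exact bit-reproducibility holds within a platform (seeded numpy, no
  threading in the engine) but is not guaranteed across BLAS
  implementations.
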