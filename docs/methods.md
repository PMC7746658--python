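# Methods

This note documents the models, procedures and numerical choices behind
`leafgan`: a CPU-complete re-implementation of a limited-data plant-disease
classification pipeline in which a conditional Wasserstein GAN with
gradient penalty (WGAN-GP), regularized by label smoothing (LSR), enlarges
a small labeled training set for a VGG16-style classifier.

## The problem and the model

Image classifiers for plant disease work well with thousands of labeled
leaves per class but overfit badly when classes have only tens of images.
The pipeline addresses this with three layers of data enrichment:

1. **Classic augmentation** — label-preserving stochastic transforms
   (rotation up to 360°, width/height shifts up to 0.3 of the image, zoom
   in [0.7, 1.3], horizontal and vertical flips) resampled every epoch, so
   the classifier never sees the same pixels twice.
2. **Conditional WGAN-GP** — a generator G(z, y) synthesizes class-y leaf
   images from Gaussian noise z; the conditioning multiplies z elementwise
   with a trainable per-class embedding row.  The critic D is dual-headed:
   an unbounded validity score trained with the Wasserstein objective
   (real labeled +1, synthetic −1, i.e. loss −E[D(x_real)] + E[D(x_fake)])
   plus the two-sided gradient penalty
   λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²] on uniform real/fake interpolates x̂, and a
   class head trained with label-smoothed cross-entropy.
3. **Label smoothing regularization** — the class loss
   L = −(1−ε)·log p(y) − (ε/N)·Σᵢ log p(i), with the sum over **all** N
   classes including y (as the formula is conventionally written; ε = 0
   recovers plain cross-entropy exactly).  In the generator update the same
   smoothed loss is applied to the critic's class output on the
   conditioning labels, so synthesized images are pushed toward smoothed
   class distributions rather than over-confident one-hot targets.

The four-regime comparison protocol trains the same classifier under:
(I) raw images only; (II) per-epoch classic augmentation; (III) augmentation
plus per-epoch synthetic images from a GAN trained with ε = 0; (IV) the
same with ε = 0.22.  All regimes share one byte-identical test set.

## Architectures

The full-scale layer plans (reproduced cell-for-cell by
`networks.shape_walk`) are: a generator mapping a 1000-d conditioned vector
through Dense → 8×8×128 and four upsample+3×3-conv stages (128, 64, 32, 3
channels) to a 128×128×3 tanh image; a critic with stride-2 3×3 convs
(16, 32 channels), an asymmetric zero-pad to 33×33, a stride-2 conv to
17×17×64, a stride-1 conv to 17×17×128 and two dense heads (1 validity
unit, 38 class units); and a VGG16 classifier (conv blocks 64-64, 128-128,
256×3, 512×3, 512×3 with max pools, global average pool to 1×1×512, dense
512, dense 38 softmax).  `base_channels` scales all widths and
`image_size` all spatial sizes, so the identical code runs desk-scale
networks for tests.

Choices the published design leaves open, resolved here as community
defaults: generator hidden layers use batch-norm + ReLU with a tanh
output; the critic uses LeakyReLU(0.2) and **no** batch-norm (the gradient
penalty is a per-sample statement; batch-norm would couple samples); the
classifier is plain VGG16 (no batch-norm, trained from scratch, softmax
output).  Convolutions use TensorFlow-style "same" padding, which is what
makes 33 → 17 under stride 2.  The embedding initializes uniform in
[0.5, 1.5] — mean 1, so conditioning starts near a pass-through of z while
classes are already distinct — and trains jointly with the generator.

## Training loop

One iteration = 5 critic updates then 1 generator update (the standard
WGAN-GP ratio; configurable).  The optimizer is RMSprop (ρ = 0.9); the
full-scale learning rate is 5e-5 for the GAN and 1e-4 for the classifier.
The gradient penalty is differentiated **exactly** with respect to the
critic's weights by double backpropagation: the package includes a small
reverse-mode autodiff engine over NumPy whose vector-Jacobian products are
themselves engine ops, so `grad(..., create_graph=True)` yields a
differentiable graph.  (Convolutions are built from a patch-extraction
primitive whose adjoint is scatter-add and vice versa, which is what makes
them twice-differentiable.)  Every stochastic choice — batch sampling,
noise draws, interpolation coefficients, augmentation parameters — is keyed
by counter-based `SeedSequence` spawn keys, so runs are bit-reproducible
and order-independent.

Synthetic images for regimes III/IV are regenerated every classifier epoch
(30 per class at full scale), not cached.  The labeling of a synthetic
image is either its conditioning label or the argmax of the critic's class
head; the full-scale procedure describes the argmax rule, but the two can
disagree (changing per-class counts), so both modes are implemented and the
disagreement rate is logged.  No rebalancing is applied after argmax
relabeling.

## Losses: numerical choices

* Probabilities are floored at 1e-12 before any log; losses are finite for
  any softmax output.  The floor also gates the gradient (zero below the
  floor).
* The gradient-penalty norm adds 1e-12 under the square root to keep the
  derivative finite at zero gradient.
* The interpolation coefficient of the penalty is uniform in [0, 1] per
  sample; λ defaults to 10.
* The class-loss weight relative to the Wasserstein + penalty terms is 1.0
  (configurable); the published description does not state a weighting.
* Argmax ties in predictions resolve to the lowest class index.
* Table-reproduction rounding is decimal half-up to two decimals; full
  precision is kept internally.

## Synthetic leaf data

Real PlantVillage-style photographs are emulated by a procedural renderer:
a filled-ellipse "leaf" with jittered radii and orientation on a textured
warm-gray background, with blurred elliptical lesions.  Class identity is
carried by base hue (spread over 0.85 of the hue circle), lesion count
(2 + class-keyed 0–3), lesion aspect ratio and lesion color;
`feature_strength` ∈ [0, 1] scales all class keying, with strength 0
producing pixel-identical images across classes for the same draw seed.
Hue jitter is ±0.01, so at strength 1 the class-hue gap exceeds the
within-class spread by an order of magnitude — classes are separable by
design, which is what lets tiny networks demonstrate the protocol.

What the generator does **not** emulate: real lesion morphology and
texture, lighting and background variation, occlusion, class imbalance in
the test set, and the visual overlap between diseases that makes the real
problem hard.  Passing desk-scale tests therefore demonstrates the
correctness and direction of the machinery (losses, training dynamics,
protocol), not field-level accuracy; the published full-scale accuracies
are shipped as reference tables, never recomputed.

The per-class split rule for directory trees is floor(fraction·n) with at
least one image kept on each side (test side only when fraction < 1).

## Desk-scale study conditions

Chosen once for one-CPU runs and used by the test suite and the acceptance
script alike:

* **GAN behavior run** — 2 classes × 30 images at 16×16, `base_channels` 2,
  noise dim 32, batch 16, learning rate 4e-4, 1,500 iterations.  At this
  scale the Wasserstein estimate rises while the critic dominates and then
  decays as the generator catches up; the check compares the trailing-100
  iteration mean against the leading-100 mean.  The learning rate is
  higher than the full-scale 5e-5 because a desk-scale run must traverse
  the same rise-and-converge trajectory in ~10³ rather than ~10⁴
  iterations.
* **Regime comparison** — 2 classes × 12 training / 40 test images at
  32×32, classifier channels 4, batch 24, learning rate 2e-4, 100 epochs
  (training-accuracy convergence at this scale), medians over 3 seeds.
  Directional claims (II ≥ I) are asserted on medians, never single runs.

## Known limitations

* The NumPy engine is single-threaded and float64; full-scale (128×128,
  38-class, 22,000-iteration) training is far outside its envelope by
  design — the full-scale specs exist for the architecture audit.
* Batch-norm uses running statistics at synthesis time; generators
  checkpointed mid-training therefore synthesize deterministically but
  with statistics that may lag the batch statistics seen in training.
* The published per-class tables are reproduced from their printed
  two-decimal recall/precision values; cells whose printed F1 disagrees
  with the recomputed harmonic mean by one unit in the last place are
  attributable to that rounding (the consistency check accounts for it).
* `AugmentConfig` brightness/contrast/sharpness defaults are the identity
  (photometric augmentation off), because the four-regime protocol lists
  only the geometric transforms; the photometric operations are available
  and documented for completeness.
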