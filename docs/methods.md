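# Methods

## The model

The package synthesises images that stand in for visual hallucinations of
different aetiologies by running activation maximisation (AM) over a
trained image classifier, optionally constrained by a trained generator.
One AM iteration is:

1. forward the current image `x` through the classifier up to a chosen
   *terminal layer*, collecting activations `a`;
2. convert `a` into an *error signal* `e` with one of three error
   functions;
3. backpropagate `e` to obtain a gradient `g = ∂⟨e, a⟩/∂v` with respect to
   the optimisation variable `v`;
4. take a normalised ascent step `v ← v + η · g / mean|g|` and project back
   into the valid range.

The optimisation variable defines the **AM type** (the veridicality axis):

* **ClassicalAM** — `v` is the image itself; pixels are updated directly
  and clipped to `[0, 1]` each step. Unconstrained pixel ascent produces
  low-veridicality, distorted imagery.
* **GenerativeAM** — `v` is a latent code `z` and every iterate is
  `decode(z)`; outputs stay on the generator's learned image manifold and
  remain realistic-looking. The code is initialised by inverting the input
  image (encoder warm start, optionally refined by gradient descent on the
  reconstruction loss), so early iterations resemble the input.

The **error function** defines the spontaneity axis:

* **Fixed** — a one-hot signal at a pre-chosen neuron; independent of the
  input, so content appears spontaneously (objective: `a_j`).
* **Deep-Dream** — `e = a`, so every active neuron reinforces itself
  (objective: `½‖a‖²`); content grows out of what the input already
  excites. The signal uses current-iteration activations; an optional flag
  restricts it to the neurons active at iteration 0.
* **Winner-Take-All** — the neuron most activated *by the original input*
  is selected once, at iteration 0, and then treated like a fixed target.
  The winner is never re-evaluated during the run; this models
  input-driven but maximally confident (non-hallucinatory) perception and
  serves as the benchmark condition.

The **terminal layer** defines the complexity axis: stopping at the top
categorical layer yields object-like content; stopping at a lower
convolutional layer yields simple geometric/textural content. At a
convolutional layer a "neuron" is a whole channel and one-hot objectives
use the channel's spatial mean (single-unit targeting is available via the
error-function API). Argmax ties break to the lowest index.

Six frozen presets map aetiologies onto these axes (see
`hallucinet.presets`); visual-loss presets additionally degrade the input
with a central Gaussian blur composited through a soft circular mask whose
outside is bitwise untouched. Blur geometry (radius 40% of the short side,
σ 10%, 5% feather) is configurable; the defaults were chosen to cover the
central visual field while leaving a clearly intact periphery.

## Fixture subsystem

Everything is testable at desk scale through a procedural fixture stack:

* **Dataset** — 8 shape/texture categories (circle, square, triangle,
  star, cross, horizontal stripes, checkerboard, ring) rendered
  analytically at 32×32 with seeded within-class jitter: position ±15% of
  the image side, scale ±20%, fully random contrasting fore/background
  colours, and σ=0.01 pixel noise. Rendering is bitwise deterministic given
  (dataset seed, category, instance index). Default training size is 200
  samples per class with a fixed 80/20 per-class holdout.
* **Classifier** — a 3-conv-block CNN (16/32/64 channels, 3×3 kernels,
  2×2 max-pooling) with named layers `conv1..conv3, fc_top`; `fc_top` is
  the pre-softmax categorical layer. Aliases map the vocabulary of
  AlexNet-scale networks onto the fixture net (`fc8→fc_top`,
  `conv4→conv2`) so presets written in that vocabulary run unchanged.
  Training: Adam (lr 2e-3 with step decay), 25 epochs, softmax
  cross-entropy, with light augmentation (box smoothing of half of each
  batch, contrast jitter toward the batch mean, σ=0.025 pixel noise) so
  the classifier stays reliable on the softer images the generator
  produces. Typical held-out accuracy ≈ 0.97.
* **Generator** — a mean-centred dense image codec:
  `decode(z) = clip(W z + b + mean_image)` with a 192-dimensional code and
  a mirror-image affine encoder, trained as a reconstructing autoencoder
  (MSE, Adam lr 3e-3 with decay, 400 epochs). Valid codes live in the
  per-dimension box `[q01, q99]` of training-set codes, used for optional
  clamping during latent-space AM (on by default). Typical held-out
  per-pixel reconstruction RMS ≈ 0.063.

  This decoder is deliberately *not* an up-convolutional stack: at 32×32
  with 8 shape categories the data manifold is low-dimensional and an
  affine subspace prior captures it well, trains in ~2 minutes on one CPU
  core, and gives exact, fast latent gradients. What AM needs from the
  generator — a differentiable decoder whose range looks like training
  data — is preserved; the known cost is that the prior is global rather
  than spatially local, so it does not model texture statistics the way a
  convolutional generator would. The output clip makes `decode` valid for
  arbitrary codes; its gradient is zero for saturated pixels, the same
  convention pixel-space AM uses for clipped pixels.
* **Inception surrogate** — realism is scored with the Inception Score
  computed from a *separately trained* fixture classifier (different seed,
  no augmentation), never the network the optimiser climbs. Scoring
  realism with the optimised network itself would reward the optimisation
  trivially; an independent judge restores the intended meaning
  (recognisable to a network that had no part in the synthesis), mirroring
  the use of a separate inception network at full scale.

The layer stack behind both networks is a small hand-written NHWC
float64/float32 autodiff library (`hallucinet._autodiff`): im2col
convolutions, max-pooling, dense layers, and Adam, all bitwise
deterministic. Toy networks for gradient verification are built in double
precision; fixture training runs in single precision for speed.

## Numerical choices

* Gradient normalisation by the per-image mean absolute value makes step
  sizes comparable across layers and networks; defaults are 0.02
  (pixel-space) and 0.05 (latent-space).
* 1 000 iterations with snapshots after 10, 50, 100 and 1 000; iteration
  counting is 1-based ("after iteration t") and the possibly degraded
  input is always recorded as the iteration-0 snapshot. Latent-space runs
  with a fixed target saturate within a few hundred iterations once the
  code reaches its clamping box; pixel-space runs never fully saturate.
* No jitter, octaves, or total-variation regularisation: the loop is the
  bare ascent described above, with every deviation behind an explicit
  config field.
* Inception Score: single split, natural log, `0·log 0 := 0`;
  `IS = exp(mean KL(p(y|x) ‖ p̄))`, bounded by `[1, min(N, C)]`. The
  formula's lower bound is 1 (not 0); the implementation follows the
  formula.
* Input dependence (spontaneity proxy): Pearson correlation of flattened
  pixels, defined as 0 when either image is constant.
* WTA freezing: the winner is chosen from the original input's activations
  at iteration 0 and never re-evaluated; re-evaluating each iteration
  would let the target drift with the evolving image and blur the
  distinction from Deep-Dream.

## What the fixture experiments show — and what they do not

Passing tests demonstrate that the *mechanism* behaves as described on a
dataset whose categorical structure is fully controlled: fixed targets
convert the perceived class, winner-take-all preserves it, deep-dream
outputs stay correlated with their inputs while fixed-target outputs do
not, latent-space outputs are judged more realistic than pixel-space
outputs by an independent classifier, and top-layer outputs more than
lower-layer outputs. The fixture images lack natural-image statistics
(no clutter, occlusion, lighting, or scale hierarchy), the classifier has
8 categories rather than 1 000, and the generator's prior is far simpler
than a GAN's; absolute Inception Scores are therefore on a 1–8 scale and
are not comparable to published full-scale values, only their ordering is.

## Problem sizes

Defaults used by the test-suite and the acceptance script: 8×200 training
images; 20-input pools for conversion/preservation/spontaneity checks
(500–1 000 iterations); 32-image sets (8 categories × 4 instances) for
Inception Scores, 5 seeds at 300 iterations in the ordering test and one
full 1 000-iteration pass in the acceptance script; saturation measured on
10 runs of 1 000 iterations. The end-to-end reproducibility check runs the
demo at a reduced size (50 samples/class, 60 iterations) — determinism is
scale-invariant, so the property checked is unchanged.

## Known limitations

* The generator prior is affine; it constrains outputs to dataset-typical
  global structure but not to locally coherent texture. Full-scale runs
  through the adapter contract (any object with the ClassifierNetwork /
  GeneratorNetwork duck-type) are possible but untested here.
* Fixture-scale Inception Scores saturate near the 8-class ceiling for
  confident image sets; orderings near the ceiling (or the floor of 1) can
  have small margins, which is why ordering checks aggregate over seeds.
* The spontaneity proxy (pixel correlation) is only meaningful *within* an
  AM type: a latent-space output's correlation with the input is dominated
  by how similar the target category's shape is to the input's category,
  so deep-dream-vs-fixed comparisons are made at matched AM type, layer
  and iteration count, with fixed targets always drawn from categories
  other than the input's.
* The phase-averaged texture categories (checkerboard, stripes) lose their
  identity under latent averaging; class-mean decodes of those categories
  are not reliably recognisable.
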