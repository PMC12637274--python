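# Methods

## The model

`spatioseg` implements a hierarchical vision-transformer encoder-decoder for
multi-class semantic segmentation whose self-attention is explicitly biased
toward spatial locality. The intended use case is anatomical segmentation of
photographic screening images (the built-in benchmark emulates cervigram-style
scenes with background / outer anatomical region / nested region / lesion
labels 0-3), where boundary precision matters as much as region overlap.

Four components distinguish the architecture from a plain SegFormer-family
model:

1. **Adaptive patch weighting.** Each encoder stage tokenizes its input with
   a strided convolution, then multiplies token *t* by a learnable scalar
   `patch_weight[t]` (initialized to 1, one scalar per patch broadcast over
   channels) before layer normalization:
   `X_w = X_flat ⊙ W_patch`, `X_norm = γ ⊙ (X_w − μ)/√(σ² + ε) + β`.
   Because layer normalization is scale-invariant per token, the weight acts
   on the *relative* channel pattern through training dynamics rather than
   the post-norm magnitude; the per-patch scalar gives the model a cheap
   handle for amplifying or suppressing spatial locations at tokenization
   time.

2. **Centroid-distance attention bias.** For a stage grid of H×W patches
   (N = H·W tokens, row-major), the bias
   `B[i,j] = −‖p_i − p_j‖₂ / (max(D) + ε)`
   over integer lattice centroids `p_k = (k div W, k mod W)` is added to the
   raw attention scores of every head before the softmax. Entries lie in
   [−1, 0] with a zero diagonal, so geometrically nearer keys always receive
   at least as much prior mass; with zero scores the attention profile is
   strictly decreasing in centroid distance. The matrix is static, shared
   across batch and heads, and cached per (H, W, ε). Default ε = 1e−8; a
   1-token grid yields the zero matrix rather than an error. Lattice rather
   than pixel-space centroids are used because the max-normalization cancels
   any uniform spatial scale.

3. **2D relative positional encoding (RPE).** Each encoder layer owns two
   trainable tables of shape (2·max_rel − 1, heads); the per-head bias for a
   token pair is `B_h[y_i−y_j + S] + B_w[x_i−x_j + S]` with shift
   S = max_rel − 1. `max_rel` defaults to max(H, W) of the stage grid — the
   smallest table covering every offset. The lookup is implemented as a
   cached one-hot matrix product so the backward pass is a BLAS call. The
   fully biased score is `S″ = S + B_dist + B_rpe`, softmaxed afterwards.

4. **Depthwise MixFFN.** The feed-forward block expands channels (ratio 4 by
   default), applies GELU (exact erf form), reshapes tokens to their 2D
   grid, runs a per-channel 3×3 cross-correlation with zero same-padding
   (no cross-channel mixing), flattens, layer-normalizes, and projects back.

Encoder layers use pre-norm residual wiring, `x + Attn(LN(x))` then
`y + FFN(LN(y))` — standard for this model family; the residual placement
was an open design choice. Attention is full self-attention over all N
tokens: the square N×N bias structures require matched query/key grids,
which is incompatible with spatial-reduction attention, so the latter is
deliberately not implemented; configurations are sized to keep N manageable.

The all-MLP decoder linearly projects each stage's tokens to a common
`decoder_dim`, bilinearly upsamples (half-pixel/`align_corners=False`
convention) to the finest stage grid, concatenates, fuses with one linear
layer, projects to class logits and bilinearly upsamples to the input
resolution. Softmax is applied only at prediction time; ties in the argmax
resolve to the lowest class index (numpy convention).

## Numerical engine

The package trains on CPU using its own tape-based reverse-mode autodiff over
numpy float64 arrays (`spatioseg.autodiff`). Every primitive's backward rule
is validated against central finite differences in the test suite. Gradient
accumulation is non-mutating so buffers may alias safely; the backward walk
is iterative to handle deep graphs. Determinism: all initialization and data
ordering flows from `numpy.random.default_rng` seeds, so a fixed seed
reproduces a training history bit-for-bit on a fixed BLAS configuration.

## Training protocol

Defaults in `TrainConfig` (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| optimizer | Adam | β₁ 0.9, β₂ 0.999 |
| learning rate | 1e−4 | initial step size |
| clipnorm | 1.0 | global L2 gradient-norm ceiling |
| batch size | 1 | per gradient step |
| loss | Dice + CCE, weights 1/1 | soft Dice smoothing s = 1.0; CCE clip 1e−7 |
| epochs / steps | 600 / 1000 (+200 val) | full-scale profile (`configs/paper.yaml`) |
| plateau | factor 0.5, patience 15, floor 1e−15 | halve LR after 15 stagnant epochs |
| early stop | patience 35, restore best | halt after 35 stagnant epochs |
| checkpoint | monitor val_loss | best weights kept (in memory and on disk) |

"Improvement" for both callbacks means a strict decrease of validation loss
(min_delta = 0; ties count as stagnation). Callbacks run once per epoch.
The loss weights 1/1 are a design default — no prescription existed for the
relative weighting. The soft Dice term is
`1 − (2·Σpg + s)/(Σp + Σg + s)` averaged over classes with sums over batch
and pixels; a class absent from both prediction and truth contributes
exactly 0. All computation is float64 (full precision; no loss scaling is
needed or used).

**Desk-scale profile** (`configs/desk.yaml`, used by the test suite, the
examples and `scripts/acceptance.py`): 64×64 inputs, two stages with strides
(4, 2), widths (8, 16), one layer each, heads (1, 2), decoder width 32
(9,662 parameters); 200 generated images split 80/10/10; 20-30 epochs of
160 steps at batch size 1. These sizes are the package's canonical small
benchmark: large enough that the model must actually learn shape, colour
and containment structure, small enough to train in CPU minutes.

## Evaluation

* **Overlap**: per-class IoU, Dice, and pixel F1 from confusion counts.
  Pixel-level F1 is algebraically identical to Dice (2TP/(2TP+FP+FN)); the
  report carries both columns and the test suite asserts the identity. A
  class empty in both masks scores 1 by convention.
* **HD95**: boundaries are extracted as the 8-connected erosion difference
  (border pixels count as boundary); Euclidean distances from each boundary
  pixel of one region to the nearest of the other are computed exactly via
  the distance transform, pooled over both directions, and the 95th
  percentile is taken with linear interpolation between order statistics.
  Units: pixels. Either region empty ⇒ undefined; undefined values are
  excluded from means and counted, never penalized.
* **Aggregation**: per image, then mean over classes, then mean over images.
  Prediction wall-time is reported but never asserted (hardware-dependent).
* **Agreement**: Bland-Altman bias = mean of paired differences (a − b,
  a = predicted), SD with n−1 denominator, limits of agreement = bias ±
  1.96·SD (fixed z, not a t quantile — the conventional reporting choice),
  plus an OLS regression of differences on pair means for proportional bias.

## Synthetic generator

`spatioseg.synthio` draws scenes with a large rotated ellipse (label 1) on a
dark background, a smaller ellipse nested strictly inside it (label 2), and
0-3 irregular blobs (label 3, perturbed-radius polygons clipped to the outer
region; count distribution 30/35/25/10%). Each class gets a distinct base
colour with per-image jitter, radial illumination falloff, Gaussian blur of
edges, and pixel noise (σ = 0.03). Scenes violating containment or minimum
class area (1% of pixels per present class) are rejected and resampled, up
to 100 attempts. Augmentation covers flips, rotation (±25°), random crop
(70-95%), scaling (0.9-1.1), noise (σ = 0.02) and brightness/contrast
(±0.1 / 0.8-1.2); geometric ops transform the mask with nearest-neighbour
interpolation and fill exposed pixels with background; magnitudes are
exposed in `AUGMENT_DEFAULTS`. A super-resolution pre-augmentation slot
exists in concept only; it is intentionally a no-op (it would require
external pretrained upscaling models and is out of scope).

What the generator does *not* emulate: camera optics, specular reflection,
instrument occlusion, anatomical texture, inter-annotator variability, and
the heavy class imbalance of real screening data. Passing the benchmark
therefore demonstrates that the architecture, losses, metrics and training
machinery are correct and that the model can learn nested-region geometry
from noisy colour images — not clinical performance.

## Known limitations and open choices

* Full N² attention bounds practical input sizes; 256×256 four-stage
  configurations run but are slow on CPU (the full-scale profile is provided
  as configuration, not exercised in the test suite).
* The per-patch weight count ties a built model to its configured input
  size; weights are not resolution-transferable.
* The depthwise "convolution" follows the deep-learning cross-correlation
  convention; its impulse response is the point-reflected kernel (asserted
  in tests).
* An auxiliary boundary-distance *loss* is sometimes mentioned alongside
  distance-biased attention in the literature; here the spatial prior enters
  only through the attention-score bias, and HD95 is available as a
  validation metric instead.
* Bland-Altman analysis here is single-measurement; repeated-measures
  adaptations are out of scope.
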