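# Methods

## Model

The classifier is a dual-path convolutional network with squeeze-and-
excitation (SE) channel attention. Each path is a stack of
`conv(k×k, same padding, ReLU) → max-pool(2×2, stride 2)` blocks with
32/64/128 filters; Path A uses k = 3, Path B uses k = 5. "Same" padding is
structural, not cosmetic: the two paths must produce identical spatial grids
at every depth so their outputs can be concatenated on the channel axis
(asserted at build time). After concatenation (256 channels at 16×16 for a
128×128 input) the SE block squeezes each channel to its spatial mean,
passes the descriptor through a two-layer bottleneck
(256 → 16 → 256, reduction r = 16, both layers with biases, ReLU then
sigmoid) and rescales each channel by its gate. Global average pooling, a
128-unit ReLU dense layer and a 5-way softmax complete the network.

Choices where the architecture family leaves freedom, and what this
implementation does:

- **Conv and dense hidden activations**: ReLU throughout.
- **SE reduction ratio**: r = 16, the standard default for SE blocks.
- **SE placement**: after channel fusion for the dual variants; after the
  final conv block (before global pooling) for single-path + SE variants.
- **No batch normalization and no dropout**: every parameter is trainable
  and the parameter count has no running statistics.
- **Initialisation**: Glorot-style variance-scaling uniform, from an
  explicit seed; biases start at zero. All arithmetic is float32.

The whole network (forward and backward) is implemented directly in numpy.
Convolutions are evaluated as one GEMM per kernel row over a
width-direction sliding window of the padded input, which keeps the
contraction in BLAS with a large inner dimension; the gradient with respect
to the input is itself a convolution with the spatially flipped,
channel-transposed kernel. Backprop was validated against central-difference
numeric gradients on every parameter group. Having explicit backprop means
training, Grad-CAM and Integrated Gradients all consume exactly the same
gradient machinery.

## Training protocol

Nadam (Adam with Nesterov momentum, β₁ = 0.9, β₂ = 0.999, ε = 1e-7),
categorical cross-entropy with a 1e-7 probability floor, batch size 32, and
a buffered shuffle (buffer 1000, reshuffled each epoch — at desk-scale
dataset sizes this degenerates to a full shuffle). Four callbacks compose:

- **Early stopping**: stop after 5 epochs without a validation-loss
  improvement greater than 1e-4; best weights restored.
- **Reduce-on-plateau**: learning rate ×0.5 after 3 stagnant epochs
  (same 1e-4 threshold), floored at 1e-6 (the floor never raises the rate
  above its configured initial value).
- **Exponential decay**: ×0.96 per epoch, first applied at epoch 11
  (epochs are 1-based; "after the tenth epoch").
- **Checkpointing**: weights of the epoch with the lowest validation loss
  (any strict improvement counts, so restoration matches the history
  minimum exactly).

Plateau reductions and exponential decay compose multiplicatively; the
learning rate at epoch e is
`lr₀ · 0.96^max(0, e−10) · 0.5^(plateau events before e)`. Whether the two
schedules should compose or be exclusive is genuinely open; composition is
implemented because both callbacks are active simultaneously in the stack
this mirrors.

## Complexity accounting

Parameters: conv `(k²·C_in + 1)·C_out`, dense `(n_in + 1)·n_out`, SE
`C·⌊C/r⌋ + ⌊C/r⌋ + ⌊C/r⌋·C + C`. The closed forms are tested against
brute-force enumeration of every weight array for all six variants.
Model size is parameters × 4 bytes, reported in mebibytes (2²⁰ bytes);
287,525 float32 parameters ↔ 1.10 MB under this convention.

FLOPs (single-image inference): one multiply-accumulate is 2 FLOPs, bias
adds count 1, pooling (including the SE squeeze and the classifier's global
average pool) and activations are excluded. The SE block additionally pays
C·H·W recalibration multiplies. This convention is chosen for internal
consistency — pooling is excluded uniformly, rather than counting the SE
squeeze but not the classifier GAP — and it reproduces the qualitative
structure of the architecture's published profile: the conv paths dominate
(the 5×5 path at 25/9 the per-block cost of the 3×3 path), while SE and
classifier each stay at or below 0.01% and jointly below 0.02% of the
total. Absolute totals depend on the convention and are reported as the
profiler computes them, not forced to match any external figure.

## Synthetic data

The generator emulates the coarse visual statistics of H&E-stained
lung/colon patches in the standard class-folder layout, so the entire
pipeline is testable without downloads. Per class: an eosin-pink cytoplasm
background (shared across classes), hematoxylin-dark nuclei as soft-edged
disks with Poisson-distributed count (density in nuclei per 10⁴ px²,
class-specific radius range and colour), optional ring-shaped gland lumina,
and additive Gaussian noise (sd 0.02) clipped to [0, 1]. Two "benign-like"
classes get sparse regular structure (ordered gland rings, small pale
nuclei: densities 18–22); three "malignant-like" classes get dense
irregular hyperchromatic nuclei (densities 45–75). Because the background
distribution is identical everywhere, the only class-discriminative signal
lives in the planted structures, whose pixel support is recorded as a mask —
this is what makes the Grad-CAM localisation check meaningful: a model that
attends to the background is attending to noise.

Each image gets an independent child seed spawned from the master seed, so
any subset is reproducible and PNG output is byte-identical across runs.
What the generator does **not** model: stain/batch variation, tissue
folds and artefacts, whole-slide context, or any real histological
morphology. Passing the desk-scale tests therefore demonstrates that the
implementation is correct and the pipeline end-to-end trainable, not that
the architecture reaches any particular accuracy on real histopathology.

Default study conditions for the end-to-end check: 200 images per class at
128×128, generator seed 0, 60/20/20 stratified split (largest-remainder
allocation per class), dual-path + SE variant, standard protocol. The
model converges within three epochs on this separable palette; the
end-to-end suite trains for four and requires ≥95% held-out accuracy and a
mean Grad-CAM in-mask mass ≥60% (masks dilated by a radius-10 disk to
absorb the 8-pixel granularity of the 16×16 saliency grid, measured over a
stride-10 sample of correctly classified test images). Observed at these
conditions: 98.5% test accuracy and 0.82 mean in-mask mass.

Small-image toy fixtures (32×32, 8/16 filters) use an easier palette with
class-distinct backgrounds, because at 32×32 the realistic defaults carry
too little per-crop signal to train a confident toy model in seconds.

## Explainability

- Gradients for both Grad-CAM and Integrated Gradients are taken w.r.t. the
  **pre-softmax logit** of the target class.
- **Grad-CAM** defaults to the recalibrated fused feature map (the last
  spatial representation). Maps are ReLU-clipped, bilinearly upsampled and
  max-normalized (an all-zero map stays zero).
- **Integrated Gradients** uses a black (all-zeros) baseline and a midpoint
  Riemann sum; m = 64 by default, 256 where the completeness axiom is
  asserted. On a trained toy model the relative completeness gap at m = 256
  is a few 1e-4 (the floor is float32 rounding plus the ReLU/max-pool kinks
  of the path integral, so the gap does not shrink beyond that).
- **SE attention** is a per-channel vector; the spatial "heatmap" drawn in
  composites is the gate-weighted channel sum of the fused map, documented
  as an interpretation since a channel vector has no canonical spatial
  layout. Top-k channels use a stable sort (ties → lowest index).
- Signed IG views are clipped at the 99th absolute percentile and mapped
  [−1, 1] → [0, 1]; overlays alpha-blend a matplotlib colormap.

## Degenerate inputs and numerical edges

- Sigmoid gates are mathematically in (0, 1); in float arithmetic they
  saturate to exactly 0/1 beyond |logit| ≈ 37, so gate-interval assertions
  hold for moderate weight magnitudes.
- Row-normalised confusion rows for classes absent from the truth are NaN
  with a warning; zero-denominator precision/recall yield 0 with a warning;
  single-class ROC yields NaN AUC with a warning.
- Split fractions must be positive and sum to 1 (1e-9); classes too small
  to appear in all three splits raise an error naming the class.
- Non-finite training loss aborts with the epoch and batch index.

## Known limitations

- Pure-numpy training is CPU-bound: roughly 2–3 minutes per epoch at the
  600-image/128×128 study conditions on one core. The implementation is
  meant for exactness and auditability at desk scale, not throughput.
- The canonical configuration's absolute parameter and GFLOP totals
  (393,877 / 1.25 GFLOPs) follow from the stated widths and the documented
  conventions; published figures for this architecture family vary with
  counting conventions and unstated configuration details, so only
  convention-independent structure (shares, ratios, arithmetic) is asserted.
- No stain normalization, no whole-slide tiling, no pretrained backbones,
  no wall-clock benchmarking.
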