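# Methods

## The model

`usformer` implements a lightweight single-stage 3D segmentation network
for low-contrast volumetric MRI (the motivating application is left-atrium
segmentation in late gadolinium-enhancement cardiac MRI). The network is a
U-shaped encoder–decoder over full volumes: the encoder has three
convolutional stages followed by two transformer stages, the decoder is
purely convolutional with skip connections at every resolution, and a
1×1×1 head with a logistic squashing emits a voxel-wise probability map the
same size as the input. Thresholding that map (default 0.5) yields the
predicted mask in one stage — there is no ROI-localization pass and no
post-processing.

### Transposed attention

The transformer stages use channel-wise ("transposed") attention. With the
layer-normalized feature grid flattened to matrices Q, K, V ∈ R^{n×Ĉ}
(n voxels, Ĉ channels, each obtained through a bias-free 1×1×1 convolution),
the attention output is

    A(V, K, Q) = V · σ(KᵀQ)

where σ is a column-wise softmax over the Ĉ×Ĉ score matrix. Because the
scores live in channel space, the cost is O(Ĉ²n) rather than the O(n²Ĉ) of
spatial self-attention, and no n×n intermediate is ever materialized: peak
auxiliary memory is O(nĈ + Ĉ²). This is what makes global context affordable
on full 3D volumes. Column-wise softmax makes every output channel a convex
combination of the value channels; each softmax column sums to 1.

A transformer block is the standard pre-norm pair of sub-blocks, each with a
residual pathway:

    y = x + W_o · A(V, K, Q)           (attention sub-block)
    z = y + W_2 · relu(W_1 · LN(y))    (feed-forward sub-block, width ⌈2Ĉ⌉)

Residual connections are included as a design choice: without them the
blocks at depth are effectively untrainable. A fixed softmax temperature is
configurable but defaults to 1 (off). A single attention head is used.

### Stage layout and parameter budget

Default channel widths are C1..C5 = 16, 32, 64, 128, 256, all convolutions
3×3×3 with "same" padding, pooling 2×2×2 max, upsampling by learnable 2×2×2
transposed convolution. Encoder conv stages contain two conv→instance-norm→
relu units each. Transformer stages lift channels with one 3×3×3 conv, run
the transformer block, and end with one more conv before pooling (encoder
level 4) or upsampling (bottleneck). Decoder levels concatenate the skip and
apply **one** conv unit (2C→C). Where the stage layout was genuinely open we
fixed it by the parameter budget: with one decoder conv per level the
default configuration has 5,718,049 trainable parameters (≈5.7 M, the
published ballpark for this architecture family); a second decoder conv
would push it to ≈6.3 M. `usformer summary` prints the per-stage breakdown.

Because of the four poolings, spatial dimensions must be divisible by 16;
`pad_to_multiple` pads with the per-volume minimum intensity (closer to MRI
background than zero) and records the padding so predictions are cropped
back exactly. Inputs are normalized per volume to zero mean and unit SD
before the network. Note that a bottleneck grid needs at least 2 voxels per
axis for meaningful instance-norm statistics, i.e. inputs of at least 32
voxels per axis are recommended.

## Objective

    L_seg = L_dice + λ · L_BCE
    L_dice = 1 − (2·Σ Y·Ŷ + ε) / (Σ Y + Σ Ŷ + ε),   ε = 1e-5
    L_BCE  = mean over voxels of −[Y log Ŷ + (1−Y) log(1−Ŷ)]

λ defaults to 1 (the value selected by the original ablation over
{0, 0.1, 0.5, 0.9, 1, 10, 100}, exported as `LAMBDA_GRID`). The dice
denominator is implemented as the soft-dice sum ΣY + ΣŶ; a literal set
union would make perfect overlap score −1 and is inconsistent with the
evaluation dice 2TP/(2TP+FN+FP). The ε smoothing keeps empty masks finite
(the original formulation is silent on both points, as it is on the BCE
reduction; the mean keeps λ comparable across volume sizes). The dice term
is invariant to appending background to both inputs; BCE is not — this
asymmetry is the class-imbalance argument for combining them.

Gradients are hand-derived (`seg_loss_grad`) and checked against finite
differences in the tests.

## Numerical core

No deep-learning framework is used: layers (3D conv, transposed conv, max
pool, instance/layer norm, pointwise convs, the attention itself) are
implemented on NumPy in channels-last layout `(H, W, Z, C)` with explicit
reverse-mode gradients, so channel mixing reduces to BLAS matrix products.
Convolution runs as one GEMM per kernel offset on shifted views of the
padded input. Mini-batches are realized by gradient accumulation, which is
exactly batched SGD here because all normalization is per-sample. Every
layer's backward pass is validated against central finite differences in
float64; forward passes are float32 in training.

One numerical caveat found during validation: at voxels where every channel
is exactly zero (possible after relu on padded background) the channel
layer-norm is locally near-singular (1/√eps scale, eps = 1e-5), which makes
naive finite differences at such points converge slowly — the analytic
gradients are nevertheless exact, as the eps-sweep in the tests shows.

## Training and inference

SGD with momentum 0.9 (weight decay 0 by default), 200 epochs, cosine
annealing lr(e) = lr0·(1 + cos(πe/E))/2 from lr0 = 0.001 to 0 — the
standard half-cosine, since the exact formula was unspecified. Batch size
defaults to 2 (unstated in the original recipe; configurable). Augmentation
is applied on the fly with probability 0.5 per scan: one in-plane affine
draw — scale ∈ (0.5, 1.5), rotation ∈ (−25°, 25°), translation ∈ (−10, 10)
pixels — applied identically to every IJ (axial) slice, linear resampling
for the image and nearest-neighbour for the mask. One draw per scan (not
per slice) preserves inter-slice coherence; the 50% gate covers the whole
transform rather than each component. Fill values are the volume minimum /
background. When a validation set is supplied, the weights with the best
validation dice are retained. Training is bit-reproducible given (seed,
data, config) under a fixed thread policy.

Inference thresholds the probability map at 0.5 by default ("exceeds"
semantics: a probability of exactly 0.5 is background).

## Evaluation metrics

Dice = 2TP/(2TP+FN+FP) over the whole volume. Surface metrics use surface
voxels: foreground voxels with at least one background 6-neighbour, with
the array border counting as background. Distances are Euclidean between
voxel centres in physical millimetres (anisotropic spacing honoured),
computed with a KD-tree and verified against O(|P||G|) all-pairs oracles:

    HD   = max{ max_p min_g d(p,g),  max_g min_p d(p,g) }      (full max, not HD95)
    ASSD = ( Σ_g min_p d(p,g) + Σ_p min_g d(p,g) ) / (n_G + n_P)

n_G, n_P are the surface cardinalities (the standard ASSD reading). Dice of
two empty masks is defined as 1.0 with a warning; surface metrics on an
empty surface raise. Aggregates report mean and population SD across scans.

## Synthetic phantoms

The phantom generator reproduces the properties that make the real task
hard, so the whole pipeline is exercisable without clinical data:

- **class imbalance** — foreground fraction constrained to [0.005, 0.05]
  of a 64×64×32 grid at 1.25×1.25×2.5 mm spacing;
- **low contrast** — foreground/background mean gap of 1.5 noise-SD units,
  Gaussian-blurred (σ = 1 voxel) before additive Gaussian noise;
- **tubular appendages** — 2–4 curved tubes (radius 1.2–2.2 voxels, length
  8–16) grown outward from the ellipsoid body, plus an optional lobe,
  emulating pulmonary veins and the atrial appendage.

Masks are resampled (bounded retries) until single-6-connected and within
the foreground bounds — regeneration rather than morphological repair keeps
the geometry honest. Phantoms are bit-reproducible from (spec, seed).

What the phantoms do **not** model: Rician noise statistics (Gaussian is
used for simplicity), fibrosis/enhancement texture, vendor intensity
variation, anatomically faithful atrial shape, and multi-orientation
acquisitions. Passing the end-to-end tests therefore demonstrates that the
architecture, objective, augmentation, optimizer and metrics interoperate
correctly and can segment small low-contrast connected structures — not
clinical-grade accuracy on real LGE MRI.

## Desk-scale problem sizes

The test suite trains reduced configurations chosen to exercise every
component at interactive cost: channels 4/8/16/32/64 on twenty 64×64×32
phantoms (five held out, 30 epochs) for the end-to-end run, and channels
2/4/8/16/32 on 32×32×16 phantoms for the data-efficiency sweep (training
sizes 4 vs 16, three replicates, 30 epochs). At these reduced volume and
batch statistics the published lr₀ = 0.001 under-trains within the epoch
budget, so the desk-scale runs use lr₀ = 0.05–0.08 with the same cosine
schedule; the full-scale default remains 0.001. The full-size configuration
is exercised for construction, parameter accounting and FLOP estimation,
not training.

## Known limitations

- Single-class, single-channel volumes only; 2D operation is out of scope.
- No GPU path; training the full configuration on clinical volumes is far
  outside this implementation's performance envelope.
- FLOP totals are analytic estimates of one forward pass; the input size
  behind any particular published GFLOP figure is not reconstructable, so
  the estimator reports per-shape values instead of matching one number.
- No resampling between spacings: masks are evaluated on their native grid.
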