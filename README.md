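# usformer

Single-stage 3D segmentation of small, low-contrast structures in
volumetric MRI — the motivating task is left-atrium (LA) delineation in
late gadolinium-enhancement (LGE) cardiac MRI, where the target occupies a
few percent of the volume, boundaries are faint, and slender pulmonary-vein
/ appendage structures must be captured. The package is aimed at
researchers who want a complete, dependency-light, CPU-runnable reference
implementation of this architecture family together with its training
recipe, surface-distance evaluation suite, and a synthetic phantom
generator that makes the whole pipeline testable without clinical data.

## The model

A U-shaped 3D encoder–decoder operating on whole volumes in one pass (no
ROI-localization stage, no post-processing). The encoder has three
convolutional stages followed by two transformer stages whose attention is
*transposed* — computed over channels rather than voxels. With the
layer-normalized features flattened to Q, K, V ∈ ℝ^{n×Ĉ} (n voxels, Ĉ
channels):

    A(V, K, Q) = V · σ(KᵀQ)

where σ is a column-wise softmax over the Ĉ×Ĉ score matrix. The cost is
O(Ĉ²n) instead of the O(n²Ĉ) of spatial self-attention, so global context
stays affordable on full 3D grids. Training minimizes

    L_seg = L_dice + λ·L_BCE,   λ = 1,

with SGD + momentum under cosine annealing (lr₀ = 0.001, 200 epochs for the
full-scale recipe) and 50%-probability in-plane affine augmentation (scale
(0.5, 1.5), rotation (−25°, 25°), translation (−10, 10) px). Evaluation
reports 3D Dice, full Hausdorff distance and average symmetric surface
distance in millimetres on the native grid. The network, including all
gradients, is implemented directly on NumPy; see `docs/methods.md`.

## Worked example

Generate a small phantom dataset, inspect the architecture, train a reduced
model, and evaluate:

```sh
usformer phantom --n 3 --seed 7 --out phantoms/
usformer summary --input-shape 96x96x48
```

`summary` prints the parameter count and the per-stage FLOP table for the
default configuration:

```
trainable parameters: 5718049
        enc1      6.6249 GFLOPs
        enc2      4.6183 GFLOPs
        enc3      2.3012 GFLOPs
        enc4      1.4338 GFLOPs
  bottleneck      0.7161 GFLOPs
        dec4      1.5866 GFLOPs
        dec3      3.1753 GFLOPs
        dec2      6.3595 GFLOPs
        dec1     12.7544 GFLOPs
        head      0.0164 GFLOPs
total forward FLOPs @ 96x96x48: 39.59 G
```

i.e. ≈5.7 M trainable parameters — the lightweight end of 3D segmentation
networks (nnU-Net-class baselines carry 3–8× more).

In Python, a desk-scale end-to-end run (reduced channel widths, synthetic
phantoms) looks like:

```python
import numpy as np
from usformer import (UsformerConfig, build_usformer, TrainConfig, fit,
                      predict, dice3d, generate_dataset)

items, _ = generate_dataset(25, seed=101)          # 64x64x32 phantoms
train_set, test_set = items[:20], items[20:]
net = build_usformer(UsformerConfig(channels=(4, 8, 16, 32, 64)), seed=7)
net, hist = fit(net, train_set, TrainConfig(epochs=30, seed=13, initial_lr=0.05))
dices = [dice3d(predict(net, v, 0.5), m) for v, m in test_set]
print(np.mean(dices))
```

which trains in a few minutes on one CPU core and prints a held-out mean
dice above 0.85: the pipeline separates the low-contrast foreground from
noise well beyond what per-voxel thresholding of these phantoms could
achieve. `usformer train / predict / evaluate` expose the same workflow on
NIfTI/NRRD files, and `evaluate` writes a per-scan CSV of dice, HD (mm) and
ASSD (mm) with aggregate rows.

## Layout

| module | contents |
|---|---|
| `usformer.volumes` | `Volume3D`, NIfTI/NRRD I/O, padding/cropping, normalization |
| `usformer.nn` | NumPy layer framework with hand-derived gradients |
| `usformer.net` | the architecture, transposed attention, parameter/FLOP accounting |
| `usformer.objective` | dice + λ·BCE loss and its gradient |
| `usformer.metrics` | Dice, Hausdorff, ASSD (mm, spacing-aware), report aggregation |
| `usformer.augment` | in-plane affine augmentation |
| `usformer.train` | SGD + cosine schedule, fit/predict, learning-curve protocol |
| `usformer.phantoms` | seeded synthetic LGE-like phantom generator |
| `usformer.config`, `usformer.cli` | strict YAML config and the `usformer` CLI |
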