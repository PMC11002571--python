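"""Training loop, single-stage inference, and the training-set-size sweep.

Optimization follows the original recipe: SGD with momentum on the combined
dice + BCE loss, cosine-annealed learning rate from 0.001 over 200 epochs,
augmentation applied on the fly with 50% probability, and a probability
threshold of 0.5 at inference. Inference is single-stage: the whole volume
is normalized, padded to a 16-divisible grid, pushed through the network
once, cropped back and thresholded — no ROI cropping and no post-processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .augment import AugmentConfig, apply_inplane_affine, sample_affine
from .metrics import dice3d
from .net import DOWNSAMPLE_FACTOR, Usformer, UsformerConfig, build_usformer
from .objective import LossConfig, seg_loss_grad
from .volumes import Volume3D, crop_by_record, pad_to_multiple, znormalize

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "cosine_lr",
    "fit",
    "predict",
    "predict_probabilities",
    "learning_curve",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults mirror the published recipe."""

    initial_lr: float = 0.001
    epochs: int = 200
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 2
    threshold: float = 0.5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    augment_enabled: bool = True

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def cosine_lr(epoch: int, total: int, lr0: float) -> float:
    """Half-cosine annealing: lr0 * (1 + cos(pi * epoch / total)) / 2."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not (0 <= epoch <= total):
        raise ValueError(f"epoch {epoch} outside [0, {total}]")
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * epoch / total))


def _prepare(vol_data: np.ndarray) -> tuple[np.ndarray, "object"]:
    """Normalize and pad to the network's downsampling multiple."""
    v = Volume3D(znormalize(vol_data))
    padded, record = pad_to_multiple(v, DOWNSAMPLE_FACTOR)
    return padded.data.astype(np.float32)[None], record


class _Momentum:
    def __init__(self, params, momentum, weight_decay):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= lr * g
            p.data += v
            p.grad[...] = 0.0


def fit(
    net: Usformer,
    train_set: list[tuple[Volume3D, np.ndarray]],
    cfg: TrainConfig,
    val_set: list[tuple[Volume3D, np.ndarray]] | None = None,
) -> tuple[Usformer, TrainHistory]:
    """Train ``net`` in place; deterministic given (seed, data, config).

    ``train_set`` holds (volume, binary mask) pairs on 16-divisible-compatible
    grids (padding is applied internally). When a validation set is given,
    the weights with the best validation dice are restored at the end.
    """
    if not train_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    params = net.parameters()
    opt = _Momentum(params, cfg.momentum, cfg.weight_decay)
    history = TrainHistory()
    best = (-1.0, None)

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.initial_lr)
        order = rng.permutation(len(train_set))
        losses = []
        pending = 0
        for idx in order:
            vol, mask = train_set[idx]
            data, m = vol.data, mask
            if cfg.augment_enabled:
                p = sample_affine(rng, cfg.augment)
                data, m = apply_inplane_affine(data, m, p)
            x, record = _prepare(data)
            pred = net.forward(x, training=True)
            target, _ = _prepare_mask(m, record)
            value, grad = seg_loss_grad(pred[0], target, cfg.loss)
            if not np.isfinite(value):
                raise FloatingPointError(f"loss diverged at epoch {epoch} (got {value})")
            losses.append(value)
            net.backward(grad.astype(np.float32)[None] / cfg.batch_size)
            pending += 1
            if pending == cfg.batch_size:
                opt.step(lr)
                pending = 0
        if pending:
            opt.step(lr)
        history.loss.append(float(np.mean(losses)))
        history.lr.append(lr)
        if val_set:
            dices = [
                dice3d(predict(net, vol, cfg.threshold), m) for vol, m in val_set
            ]
            vd = float(np.mean(dices))
            history.val_dice.append(vd)
            if vd > best[0]:
                best = (vd, [p.data.copy() for p in params])
    if val_set and best[1] is not None:
        for p, w in zip(params, best[1]):
            p.data = w
    return net, history


def _prepare_mask(mask: np.ndarray, record) -> tuple[np.ndarray, None]:
    pads = record.pad_width
    if any(lo or hi for lo, hi in pads):
        mask = np.pad(mask, pads, mode="constant", constant_values=0)
    return mask.astype(np.float64), None


def predict_probabilities(net: Usformer, vol: Volume3D) -> np.ndarray:
    """Full-volume probability map on the input grid (pad, forward, crop)."""
    x, record = _prepare(vol.data)
    prob = net.forward(x)[0]
    return crop_by_record(prob, record)


def predict(net: Usformer, vol: Volume3D, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: voxels whose probability exceeds ``threshold``."""
    prob = predict_probabilities(net, vol)
    return (prob > threshold).astype(np.uint8)


def learning_curve(
    pool: list[tuple[Volume3D, np.ndarray]],
    sizes: list[int],
    replicates: int,
    test_set: list[tuple[Volume3D, np.ndarray]],
    cfg: TrainConfig,
    net_cfg: UsformerConfig,
    seed: int = 0,
) -> list[dict]:
    """Mean test dice as a function of training-set size.

    For each size, ``replicates`` training subsets are drawn at random from
    the pool, a fresh network is trained from scratch on each, and the mean
    test dice over replicates is reported — the protocol behind
    data-efficiency curves.
    """
    if any(s > len(pool) for s in sizes):
        raise ValueError("requested size exceeds pool size")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        dices = []
        for rep in range(replicates):
            subset_idx = rng.choice(len(pool), size=size, replace=False)
            subset = [pool[i] for i in subset_idx]
            rep_cfg = TrainConfig(**{**asdict_shallow(cfg), "seed": int(rng.integers(2**31))})
            net = build_usformer(net_cfg, seed=int(rng.integers(2**31)))
            net, _ = fit(net, subset, rep_cfg)
            d = [dice3d(predict(net, vol, cfg.threshold), m) for vol, m in test_set]
            dices.append(float(np.mean(d)))
        rows.append({"size": size, "mean_dice": float(np.mean(dices)), "dice": dices})
    return rows


def asdict_shallow(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["loss"] = cfg.loss
    d["augment"] = cfg.augment
    return d


def save_checkpoint(path, net: Usformer, cfg: TrainConfig | None = None) -> None:
    """Self-describing checkpoint: weights + architecture + training config."""
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    meta = {
        "net": {**asdict(net.cfg)},
        "train": asdict(cfg) if cfg is not None else None,
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[Usformer, dict]:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        net_cfg = meta["net"]
        net_cfg["channels"] = tuple(net_cfg["channels"])
        net = build_usformer(UsformerConfig(**net_cfg))
        params = net.parameters()
        for i, p in enumerate(params):
            p.data = z[f"param_{i}"].astype(np.float32)
    return net, meta
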