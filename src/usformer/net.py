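"""The Usformer architecture.

A U-shaped 3D encoder-decoder: the encoder has three convolutional stages
followed by two transformer stages whose attention operates over *channels*
rather than spatial positions ("transposed attention"). For an input of n
voxels and C channels the attention score matrix is C x C, so the cost is
O(C^2 n) instead of the O(n^2 C) of conventional spatial self-attention —
the property that makes full-volume, single-stage 3D segmentation tractable.

Given layer-normalized features flattened to Q, K, V in R^{n x C}, the
attention output is

    A(V, K, Q) = V . softmax(K^T Q)

with the softmax taken column-wise, so every output channel is a convex
combination of the value channels. Residual pathways wrap both the attention
and the feed-forward sub-blocks (without them blocks at depth do not train).

The decoder mirrors the encoder with skip connections at every resolution
and is purely convolutional; a 1x1x1 head with a logistic squashing emits a
probability map the same size as the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    ChannelLayerNorm,
    Conv3d,
    InstanceNorm3d,
    MaxPool3d,
    Module,
    Parameter,
    PointwiseConv3d,
    ReLU,
    Sequential,
    Sigmoid,
    TransposedConv3d,
)

__all__ = [
    "UsformerConfig",
    "TransposedAttention",
    "FeedForward",
    "TransformerBlock",
    "Usformer",
    "build_usformer",
    "count_parameters",
    "estimate_flops",
    "flops_breakdown",
    "attention_flops",
]

DOWNSAMPLE_FACTOR = 16  # four 2x2x2 poolings


@dataclass
class UsformerConfig:
    """Architecture hyperparameters.

    channels : five stage widths C1..C5 (default 16, 32, 64, 128, 256)
    conv_kernel : isotropic conv kernel size (odd; default 3)
    pool_kernel : pooling / upsampling factor per stage (default 2)
    convs_per_stage : convs in each encoder conv stage (default 2)
    decoder_convs : convs in each decoder level after skip concat (default 1)
    ffn_expansion : hidden-width multiplier of the feed-forward network
    attention_temperature : divisor applied to the score matrix (1.0 = off)
    """

    channels: tuple[int, int, int, int, int] = (16, 32, 64, 128, 256)
    conv_kernel: int = 3
    pool_kernel: int = 2
    convs_per_stage: int = 2
    decoder_convs: int = 1
    ffn_expansion: float = 2.0
    attention_heads: int = 1
    attention_temperature: float = 1.0
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)  # type: ignore[assignment]
        if len(self.channels) != 5:
            raise ValueError(f"channels must list five stage widths, got {self.channels}")
        if any(c < 1 for c in self.channels):
            raise ValueError("channel counts must be positive")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")
        if self.convs_per_stage < 1 or self.decoder_convs < 1:
            raise ValueError("stage conv counts must be >= 1")


class TransposedAttention(Module):
    """Channel-wise attention sub-block: x + Wo . V softmax(K^T Q / tau).

    Q, K, V come from bias-free 1x1x1 convolutions of the layer-normalized
    input. The score matrix is C x C; no n x n intermediate is ever formed,
    so auxiliary memory is O(nC + C^2).
    """

    def __init__(self, channels: int, temperature: float = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.temperature = float(temperature)
        self.norm = ChannelLayerNorm(channels)
        self.wq = PointwiseConv3d(channels, channels, bias=False, rng=rng)
        self.wk = PointwiseConv3d(channels, channels, bias=False, rng=rng)
        self.wv = PointwiseConv3d(channels, channels, bias=False, rng=rng)
        self.wo = PointwiseConv3d(channels, channels, bias=True, rng=rng)
        self.last_score_shape: tuple[int, int] | None = None
        self._cache: tuple | None = None

    def attention_scores(self, x: np.ndarray) -> np.ndarray:
        """The softmax-normalized C x C score matrix for input ``x``."""
        xn = self.norm.forward(x)
        C = self.channels
        q = self.wq.forward(xn).reshape(-1, C)
        k = self.wk.forward(xn).reshape(-1, C)
        return _softmax_cols(k.T @ q / self.temperature)

    def forward(self, x, training=False):
        C = self.channels
        spatial = x.shape[:3]
        xn = self.norm.forward(x, training=training)
        # channels-last grids flatten to the n x C matrices for free
        q = self.wq.forward(xn, training=training).reshape(-1, C)
        k = self.wk.forward(xn, training=training).reshape(-1, C)
        v = self.wv.forward(xn, training=training).reshape(-1, C)
        scores = _softmax_cols(k.T @ q / self.temperature)  # (C, C)
        self.last_score_shape = scores.shape
        a = v @ scores  # (n, C)
        out = self.wo.forward(a.reshape(*spatial, C), training=training)
        if training:
            self._cache = (q, k, v, scores, spatial)
        return x + out

    def backward(self, gy):
        q, k, v, scores, spatial = self._cache
        C = self.channels
        ga = self.wo.backward(gy).reshape(-1, C)
        gv = ga @ scores.T
        gs = v.T @ ga  # (C, C)
        # softmax (column-wise) backward
        gz = scores * (gs - (scores * gs).sum(axis=0, keepdims=True))
        gz /= self.temperature
        gq = k @ gz
        gk = q @ gz.T
        gxn = self.wq.backward(gq.reshape(*spatial, C))
        gxn += self.wk.backward(gk.reshape(*spatial, C))
        gxn += self.wv.backward(gv.reshape(*spatial, C))
        self._cache = None
        return gy + self.norm.backward(gxn)


def _softmax_cols(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def transposed_attention(v: np.ndarray, k: np.ndarray, q: np.ndarray,
                         temperature: float = 1.0) -> np.ndarray:
    """Functional core A = V softmax(K^T Q / tau) on n x C matrices."""
    if not (v.shape == k.shape == q.shape):
        raise ValueError("V, K, Q must share the same n x C shape")
    return v @ _softmax_cols(k.T @ q / temperature)


class FeedForward(Module):
    """Pointwise FFN sub-block: y + W2 relu(W1 . LN(y))."""

    def __init__(self, channels: int, expansion: float = 2.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, int(np.ceil(expansion * channels)))
        self.norm = ChannelLayerNorm(channels)
        self.w1 = PointwiseConv3d(channels, hidden, bias=True, rng=rng)
        self.act = ReLU()
        self.w2 = PointwiseConv3d(hidden, channels, bias=True, rng=rng)

    def forward(self, x, training=False):
        h = self.norm.forward(x, training=training)
        h = self.w1.forward(h, training=training)
        h = self.act.forward(h, training=training)
        h = self.w2.forward(h, training=training)
        return x + h

    def backward(self, gy):
        g = self.w2.backward(gy)
        g = self.act.backward(g)
        g = self.w1.backward(g)
        return gy + self.norm.backward(g)


class TransformerBlock(Module):
    """Pre-norm transposed-attention block followed by a feed-forward network."""

    def __init__(self, channels: int, ffn_expansion: float = 2.0,
                 temperature: float = 1.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.attention = TransposedAttention(channels, temperature=temperature, rng=rng)
        self.ffn = FeedForward(channels, expansion=ffn_expansion, rng=rng)

    def forward(self, x, training=False):
        y = self.attention.forward(x, training=training)
        return self.ffn.forward(y, training=training)

    def backward(self, gy):
        return self.attention.backward(self.ffn.backward(gy))


def _conv_block(cin: int, cout: int, kernel: int, n_convs: int,
                rng: np.random.Generator) -> Sequential:
    layers: list[Module] = []
    c = cin
    for _ in range(n_convs):
        layers += [Conv3d(c, cout, kernel, rng=rng), InstanceNorm3d(cout), ReLU()]
        c = cout
    return Sequential(*layers)


class Usformer(Module):
    """Full network; forward maps (1, H, W, Z) -> probabilities (1, H, W, Z).

    H, W, Z must each be divisible by 16 (use ``volumes.pad_to_multiple``).
    """

    def __init__(self, cfg: UsformerConfig | None = None, seed: int = 0):
        cfg = cfg or UsformerConfig()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        C1, C2, C3, C4, C5 = cfg.channels
        k, n = cfg.conv_kernel, cfg.convs_per_stage
        # encoder: three conv stages
        self.enc1 = _conv_block(cfg.in_channels, C1, k, n, rng)
        self.enc2 = _conv_block(C1, C2, k, n, rng)
        self.enc3 = _conv_block(C2, C3, k, n, rng)
        self.pool = MaxPool3d(cfg.pool_kernel)
        # encoder transformer stage (level 4): lift to C4, transformer, conv
        self.enc4_lift = _conv_block(C3, C4, k, 1, rng)
        self.enc4_tf = TransformerBlock(C4, cfg.ffn_expansion,
                                        cfg.attention_temperature, rng)
        self.enc4_conv = _conv_block(C4, C4, k, 1, rng)
        # bottleneck transformer stage: lift to C5, transformer, conv
        self.bott_lift = _conv_block(C4, C5, k, 1, rng)
        self.bott_tf = TransformerBlock(C5, cfg.ffn_expansion,
                                        cfg.attention_temperature, rng)
        self.bott_conv = _conv_block(C5, C5, k, 1, rng)
        # decoder: upsample, concat skip, conv block
        self.up4 = TransposedConv3d(C5, C4, cfg.pool_kernel, rng=rng)
        self.dec4 = _conv_block(2 * C4, C4, k, cfg.decoder_convs, rng)
        self.up3 = TransposedConv3d(C4, C3, cfg.pool_kernel, rng=rng)
        self.dec3 = _conv_block(2 * C3, C3, k, cfg.decoder_convs, rng)
        self.up2 = TransposedConv3d(C3, C2, cfg.pool_kernel, rng=rng)
        self.dec2 = _conv_block(2 * C2, C2, k, cfg.decoder_convs, rng)
        self.up1 = TransposedConv3d(C2, C1, cfg.pool_kernel, rng=rng)
        self.dec1 = _conv_block(2 * C1, C1, k, cfg.decoder_convs, rng)
        self.head = PointwiseConv3d(C1, cfg.out_channels, bias=True, rng=rng)
        self.squash = Sigmoid()
        self._skip_channels = (C1, C2, C3, C4)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected input of shape (1, H, W, Z), got {x.shape}")
        if any(d % DOWNSAMPLE_FACTOR for d in x.shape[1:]):
            raise ValueError(
                f"spatial dims must be divisible by {DOWNSAMPLE_FACTOR}, got {x.shape[1:]}"
            )
        # channels-first at the API boundary, channels-last internally
        x = np.ascontiguousarray(np.moveaxis(x, 0, -1))
        # one pool instance per level: each keeps its own backward cache
        s1 = self.enc1.forward(x, training)
        s2 = self.enc2.forward(self.pool.forward(s1, training), training)
        s3 = self.enc3.forward(self._pool(1).forward(s2, training), training)
        e4 = self.enc4_lift.forward(self._pool(2).forward(s3, training), training)
        e4 = self.enc4_tf.forward(e4, training)
        s4 = self.enc4_conv.forward(e4, training)
        b = self.bott_lift.forward(self._pool(3).forward(s4, training), training)
        b = self.bott_tf.forward(b, training)
        b = self.bott_conv.forward(b, training)
        d4 = self.dec4.forward(_concat(self.up4.forward(b, training), s4), training)
        d3 = self.dec3.forward(_concat(self.up3.forward(d4, training), s3), training)
        d2 = self.dec2.forward(_concat(self.up2.forward(d3, training), s2), training)
        d1 = self.dec1.forward(_concat(self.up1.forward(d2, training), s1), training)
        out = self.squash.forward(self.head.forward(d1, training), training)
        return np.ascontiguousarray(np.moveaxis(out, -1, 0))

    def _pool(self, level: int) -> MaxPool3d:
        if not hasattr(self, "_pool_layers"):
            self._pool_layers = {0: self.pool}
        if level not in self._pool_layers:
            self._pool_layers[level] = MaxPool3d(self.cfg.pool_kernel)
        return self._pool_layers[level]

    def backward(self, gy):
        C1, C2, C3, C4 = self._skip_channels
        gy = np.ascontiguousarray(np.moveaxis(np.asarray(gy, dtype=np.float32), 0, -1))
        g = self.head.backward(self.squash.backward(gy))
        g = self.dec1.backward(g)
        g_up, g_s1 = g[..., :C1], g[..., C1:]
        g = self.dec2.backward(self.up1.backward(g_up))
        g_up, g_s2 = g[..., :C2], g[..., C2:]
        g = self.dec3.backward(self.up2.backward(g_up))
        g_up, g_s3 = g[..., :C3], g[..., C3:]
        g = self.dec4.backward(self.up3.backward(g_up))
        g_up, g_s4 = g[..., :C4], g[..., C4:]
        g = self.bott_conv.backward(self.up4.backward(g_up))
        g = self.bott_tf.backward(g)
        g = self.bott_lift.backward(g)
        g_s4 = g_s4 + self._pool(3).backward(g)
        g = self.enc4_conv.backward(g_s4)
        g = self.enc4_tf.backward(g)
        g = self.enc4_lift.backward(g)
        g_s3 = g_s3 + self._pool(2).backward(g)
        g = self.enc3.backward(g_s3)
        g_s2 = g_s2 + self._pool(1).backward(g)
        g = self.enc2.backward(g_s2)
        g_s1 = g_s1 + self.pool.backward(g)
        gx = self.enc1.backward(g_s1)
        return np.ascontiguousarray(np.moveaxis(gx, -1, 0))


def _concat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape[:3] != b.shape[:3]:
        raise ValueError(f"skip-connection grids disagree: {a.shape} vs {b.shape}")
    return np.concatenate([a, b], axis=-1)


def build_usformer(cfg: UsformerConfig | None = None, seed: int = 0) -> Usformer:
    """Instantiate the network from a configuration (seeded weight init)."""
    return Usformer(cfg, seed=seed)


def count_parameters(net: Module) -> int:
    """Exact count of trainable scalars."""
    return net.n_parameters()


# ---------------------------------------------------------------------------
# analytic FLOP accounting (multiply + add counted separately: 2 per MAC)


def _conv_flops(cin: int, cout: int, kernel: int, n_vox: int, bias: bool = True) -> float:
    f = 2.0 * kernel ** 3 * cin * cout * n_vox
    if bias:
        f += cout * n_vox
    return f


def attention_flops(n_vox: int, channels: int) -> float:
    """FLOPs of one transposed-attention sub-block on n voxels, C channels.

    QKV projections (3), score matrix K^T Q, aggregation V.S and the output
    projection are each 2 n C^2: linear in n, quadratic in C.
    """
    c = channels
    proj = 3 * 2.0 * n_vox * c * c          # Q, K, V (bias-free)
    scores = 2.0 * n_vox * c * c            # K^T Q
    softmax = 3.0 * c * c                   # exp, sum, divide on C x C
    agg = 2.0 * n_vox * c * c               # V . S
    out = 2.0 * n_vox * c * c + c * n_vox   # Wo with bias
    norm = 6.0 * n_vox * c                  # layer norm
    return proj + scores + softmax + agg + out + norm


def _ffn_flops(n_vox: int, channels: int, expansion: float) -> float:
    hidden = max(1, int(np.ceil(expansion * channels)))
    return (
        2.0 * n_vox * channels * hidden + hidden * n_vox  # W1 + bias
        + n_vox * hidden                                   # relu
        + 2.0 * n_vox * hidden * channels + channels * n_vox
        + 6.0 * n_vox * channels                           # layer norm
    )


def flops_breakdown(cfg: UsformerConfig, input_shape: tuple[int, int, int]) -> dict[str, float]:
    """Per-stage analytic FLOP table for one forward pass."""
    if any(d % DOWNSAMPLE_FACTOR for d in input_shape):
        raise ValueError(f"input shape must be divisible by {DOWNSAMPLE_FACTOR}")
    C1, C2, C3, C4, C5 = cfg.channels
    k, ncv, ndc, exp = cfg.conv_kernel, cfg.convs_per_stage, cfg.decoder_convs, cfg.ffn_expansion
    n = [int(np.prod(input_shape)) // (8 ** lvl) for lvl in range(5)]

    def block(cin, cout, n_vox, n_convs):
        f, c = 0.0, cin
        for _ in range(n_convs):
            f += _conv_flops(c, cout, k, n_vox) + 8.0 * n_vox * cout  # conv + norm/relu
            c = cout
        return f

    out: dict[str, float] = {}
    out["enc1"] = block(cfg.in_channels, C1, n[0], ncv)
    out["enc2"] = block(C1, C2, n[1], ncv)
    out["enc3"] = block(C2, C3, n[2], ncv)
    out["enc4"] = (
        block(C3, C4, n[3], 1)
        + attention_flops(n[3], C4) + _ffn_flops(n[3], C4, exp)
        + block(C4, C4, n[3], 1)
    )
    out["bottleneck"] = (
        block(C4, C5, n[4], 1)
        + attention_flops(n[4], C5) + _ffn_flops(n[4], C5, exp)
        + block(C5, C5, n[4], 1)
    )
    up = lambda cin, cout, n_out: 2.0 * cin * cout * n_out + cout * n_out
    out["dec4"] = up(C5, C4, n[3]) + block(2 * C4, C4, n[3], ndc)
    out["dec3"] = up(C4, C3, n[2]) + block(2 * C3, C3, n[2], ndc)
    out["dec2"] = up(C3, C2, n[1]) + block(2 * C2, C2, n[1], ndc)
    out["dec1"] = up(C2, C1, n[0]) + block(2 * C1, C1, n[0], ndc)
    out["head"] = 2.0 * C1 * cfg.out_channels * n[0] + 5.0 * n[0]
    return out


def estimate_flops(cfg: UsformerConfig, input_shape: tuple[int, int, int]) -> float:
    """Total analytic FLOPs of one forward pass at the given input shape."""
    return float(sum(flops_breakdown(cfg, input_shape).values()))
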