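"""Architecture-level tests: attention semantics against a dense oracle,
parameter accounting against an independent closed-form count, and the
analytic FLOP model's scaling behaviour."""

import numpy as np
import pytest

from usformer.net import (
    TransposedAttention,
    TransformerBlock,
    Usformer,
    UsformerConfig,
    attention_flops,
    build_usformer,
    count_parameters,
    estimate_flops,
    transposed_attention,
)


# --------------------------------------------------------------------------
# transposed attention


def dense_attention_oracle(x, attn: TransposedAttention):
    """Brute-force evaluation of A = V softmax(K^T Q): explicit matrices,
    explicit per-column softmax, independent of the module's code path."""
    C = attn.channels
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + attn.norm.eps)
    xn = attn.norm.gamma.data * (x - mu) / sd + attn.norm.beta.data
    flat = xn.reshape(-1, C).astype(np.float64)
    q = flat @ attn.wq.weight.data.astype(np.float64)
    k = flat @ attn.wk.weight.data.astype(np.float64)
    v = flat @ attn.wv.weight.data.astype(np.float64)
    z = k.T @ q / attn.temperature
    s = np.empty_like(z)
    for col in range(C):
        e = np.exp(z[:, col] - z[:, col].max())
        s[:, col] = e / e.sum()
    a = v @ s
    out = a @ attn.wo.weight.data.astype(np.float64) + attn.wo.bias.data
    return x + out.reshape(x.shape), s


@pytest.mark.parametrize("seed", range(12))
def test_attention_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    C = int(rng.integers(1, 9))
    shape = (int(rng.integers(1, 5)), int(rng.integers(1, 5)), int(rng.integers(1, 5)), C)
    attn = TransposedAttention(C, rng=rng)
    for p in attn.parameters():
        p.data = p.data.astype(np.float64)
    x = rng.normal(size=shape)
    got = attn.forward(x)
    want, scores = dense_attention_oracle(x, attn)
    np.testing.assert_allclose(got, want, atol=1e-6)
    assert attn.last_score_shape == (C, C)
    np.testing.assert_allclose(scores.sum(axis=0), 1.0, atol=1e-6)


def test_single_channel_attention_is_value_passthrough():
    """With C = 1 the score matrix is the scalar softmax(z) = 1, so A = V."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=(24, 1))
    k = rng.normal(size=(24, 1))
    q = rng.normal(size=(24, 1))
    np.testing.assert_allclose(transposed_attention(v, k, q), v)


def test_zero_scores_average_value_channels():
    """K^T Q = 0 gives a uniform softmax: every output channel is the mean
    over the C value channels."""
    rng = np.random.default_rng(1)
    C = 5
    v = rng.normal(size=(30, C))
    zeros = np.zeros((30, C))
    out = transposed_attention(v, zeros, rng.normal(size=(30, C)))
    np.testing.assert_allclose(out, np.tile(v.mean(axis=1, keepdims=True), (1, C)))


def test_attention_scales_to_large_n_without_quadratic_memory():
    """n = 64000 voxels: an n x n score matrix would need ~16 GiB, so merely
    completing proves the C x C formulation; the score matrix stays C x C."""
    attn = TransposedAttention(4, rng=np.random.default_rng(2))
    x = np.random.default_rng(3).normal(size=(40, 40, 40, 4)).astype(np.float32)
    y = attn.forward(x)
    assert y.shape == x.shape
    assert attn.last_score_shape == (4, 4)


def test_transformer_block_identity_with_zeroed_projections():
    """Zero output projections collapse both residual branches to identity."""
    blk = TransformerBlock(6, rng=np.random.default_rng(3))
    blk.attention.wo.weight.data[...] = 0.0
    blk.attention.wo.bias.data[...] = 0.0
    blk.ffn.w2.weight.data[...] = 0.0
    blk.ffn.w2.bias.data[...] = 0.0
    x = np.random.default_rng(4).normal(size=(4, 4, 2, 6)).astype(np.float32)
    np.testing.assert_array_equal(blk.forward(x), x)


@pytest.mark.parametrize("shape", [(2, 2, 2, 3), (4, 2, 6, 3), (1, 1, 8, 3)])
def test_transformer_block_preserves_shape(shape):
    blk = TransformerBlock(3, rng=np.random.default_rng(5))
    x = np.random.default_rng(6).normal(size=shape).astype(np.float32)
    assert blk.forward(x).shape == shape


def test_gradient_reaches_every_block_parameter():
    """No dead branches: a scalar loss sends nonzero gradient to every
    parameter of the transformer block."""
    blk = TransformerBlock(2, rng=np.random.default_rng(8))
    x = np.random.default_rng(9).normal(size=(4, 4, 2, 2)).astype(np.float32)
    y = blk.forward(x, training=True)
    blk.backward(np.cos(y))  # generic upstream gradient
    for p in blk.parameters():
        assert np.any(p.grad != 0), f"dead parameter {p.name}"


# --------------------------------------------------------------------------
# full network


def test_forward_shape_and_probability_range():
    net = build_usformer(UsformerConfig(channels=(2, 4, 8, 16, 32)), seed=0)
    x = np.random.default_rng(0).normal(size=(1, 32, 32, 16)).astype(np.float32)
    y = net.forward(x)
    assert y.shape == (1, 32, 32, 16)
    assert float(y.min()) >= 0.0 and float(y.max()) <= 1.0


def test_forward_rejects_indivisible_grids():
    net = build_usformer(UsformerConfig(channels=(2, 4, 8, 16, 32)))
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 30, 32, 16), dtype=np.float32))


def test_forward_is_deterministic():
    net = build_usformer(UsformerConfig(channels=(2, 4, 8, 16, 32)), seed=1)
    x = np.random.default_rng(2).normal(size=(1, 32, 32, 16)).astype(np.float32)
    np.testing.assert_array_equal(net.forward(x), net.forward(x))


def test_config_validation():
    with pytest.raises(ValueError, match="five"):
        UsformerConfig(channels=(16, 32, 64))
    with pytest.raises(ValueError, match="odd"):
        UsformerConfig(conv_kernel=4)


def closed_form_parameter_count(cfg: UsformerConfig) -> int:
    """Independent spreadsheet-style count: sum k^3*cin*cout + cout per conv,
    2C per norm, attention 4C^2 + C (wo bias) + 2*2C (norms are in blocks),
    FFN C*h + h + h*C + C, upsample 8*cin*cout + cout, head C1 + 1."""
    C1, C2, C3, C4, C5 = cfg.channels
    k3 = cfg.conv_kernel ** 3
    u3 = cfg.pool_kernel ** 3

    def conv(cin, cout):
        return k3 * cin * cout + cout

    def block(cin, cout, n):
        total, c = 0, cin
        for _ in range(n):
            total += conv(c, cout) + 2 * cout  # conv + instance norm affine
            c = cout
        return total

    def transformer(C):
        h = int(np.ceil(cfg.ffn_expansion * C))
        attn = 2 * C + 3 * C * C + C * C + C  # LN + QKV (bias-free) + Wo with bias
        ffn = 2 * C + C * h + h + h * C + C  # LN + two pointwise convs
        return attn + ffn

    n = cfg.convs_per_stage
    total = block(cfg.in_channels, C1, n) + block(C1, C2, n) + block(C2, C3, n)
    total += block(C3, C4, 1) + transformer(C4) + block(C4, C4, 1)
    total += block(C4, C5, 1) + transformer(C5) + block(C5, C5, 1)
    prev = C5
    for c in (C4, C3, C2, C1):
        total += u3 * prev * c + c  # transposed conv
        total += block(2 * c, c, cfg.decoder_convs)
        prev = c
    total += C1 * cfg.out_channels + cfg.out_channels  # head
    return total


@pytest.mark.parametrize(
    "channels", [(2, 4, 8, 16, 32), (3, 5, 7, 11, 13), (16, 32, 64, 128, 256)]
)
def test_parameter_count_matches_independent_closed_form(channels):
    cfg = UsformerConfig(channels=channels)
    net = build_usformer(cfg)
    assert count_parameters(net) == closed_form_parameter_count(cfg)


def test_trivial_parameter_counts():
    from usformer.nn import Conv3d, PointwiseConv3d

    assert PointwiseConv3d(3, 5, bias=False).n_parameters() == 15
    assert Conv3d(1, 16, 3).n_parameters() == 27 * 1 * 16 + 16


def test_default_configuration_close_to_published_size():
    n = count_parameters(build_usformer(UsformerConfig()))
    assert n == pytest.approx(5.8e6, rel=0.10)


# --------------------------------------------------------------------------
# FLOPs


def test_single_conv_flops_closed_form():
    """One 3x3x3 conv, 1->1 channel, 4^3 input, same padding, no bias:
    2 * 27 * 64 multiply-adds."""
    cfg = UsformerConfig()
    # direct check of the conv term via the module-level formula
    from usformer.net import _conv_flops

    assert _conv_flops(1, 1, 3, 64, bias=False) == 2 * 27 * 64


def test_conv_flops_scale_with_volume():
    cfg = UsformerConfig(channels=(2, 4, 8, 16, 32))
    f1 = estimate_flops(cfg, (32, 32, 16))
    f2 = estimate_flops(cfg, (64, 64, 32))
    assert f2 / f1 == pytest.approx(8.0, rel=0.02)


def test_attention_flops_linear_in_n_quadratic_in_c():
    ns = np.array([256, 512, 1024, 2048])
    cs = np.array([8, 16, 32, 64])
    f_n = np.array([attention_flops(n, 16) for n in ns])
    f_c = np.array([attention_flops(1024, c) for c in cs])
    slope_n = np.polyfit(np.log(ns), np.log(f_n), 1)[0]
    slope_c = np.polyfit(np.log(cs), np.log(f_c), 1)[0]
    assert slope_n == pytest.approx(1.0, abs=0.1)
    assert slope_c == pytest.approx(2.0, abs=0.1)
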