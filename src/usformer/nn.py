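"""Minimal NumPy layer framework with hand-derived reverse-mode gradients.

Feature maps are single-sample channels-last arrays of shape ``(H, W, Z, C)``
(float32); the layout keeps the channel axis contiguous so channel-mixing
operations reduce to BLAS matrix products on zero-copy reshapes.
Mini-batching is realized by gradient accumulation across samples, which is
mathematically identical to batched SGD here because all normalization
inside the network is per-sample (instance norm / layer norm over channels).

Every layer caches what its backward pass needs during a training forward;
``backward`` consumes the upstream gradient, accumulates ``Parameter.grad``
and returns the gradient with respect to its input. Gradient correctness is
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv3d",
    "PointwiseConv3d",
    "TransposedConv3d",
    "MaxPool3d",
    "InstanceNorm3d",
    "ChannelLayerNorm",
    "ReLU",
    "Sigmoid",
    "SGD",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter discovery walks instance attributes recursively."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, out, seen)

    @staticmethod
    def _collect_value(value, out: list[Parameter], seen: set[int]) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                out.append(value)
        elif isinstance(value, Module):
            value._collect(out, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, out, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _offsets(k: int):
    for a in range(k):
        for b in range(k):
            for c in range(k):
                yield a, b, c


class Conv3d(Module):
    """3D convolution, stride 1, "same" zero padding.

    Implemented as one channel-mixing GEMM per kernel offset on shifted
    views of the padded input; weight layout ``(k^3, cin, cout)``.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("conv kernel must be odd for 'same' padding")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, kernel
        fan_in = kernel ** 3 * cin
        self.weight = Parameter(_he_init(rng, (kernel ** 3, cin, cout), fan_in), "conv.weight")
        self.bias = Parameter(np.zeros(cout), "conv.bias") if bias else None
        self._xp: np.ndarray | None = None

    def forward(self, x, training=False):
        H, W, Z, cin = x.shape
        assert cin == self.cin, (cin, self.cin)
        p = self.k // 2
        xp = np.pad(x, ((p, p), (p, p), (p, p), (0, 0)))
        if training:
            self._xp = xp
        y: np.ndarray | None = None
        for idx, (a, b, c) in enumerate(_offsets(self.k)):
            xv = xp[a:a + H, b:b + W, c:c + Z]
            t = np.tensordot(xv, self.weight.data[idx], axes=([3], [0]))
            y = t if y is None else y + t
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, gy):
        xp = self._xp
        H, W, Z, _ = gy.shape
        p = self.k // 2
        gxp = np.zeros_like(xp)
        for idx, (a, b, c) in enumerate(_offsets(self.k)):
            xv = xp[a:a + H, b:b + W, c:c + Z]
            self.weight.grad[idx] += np.tensordot(xv, gy, axes=([0, 1, 2], [0, 1, 2]))
            gxp[a:a + H, b:b + W, c:c + Z] += np.tensordot(
                gy, self.weight.data[idx], axes=([3], [1])
            )
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 1, 2))
        self._xp = None
        return gxp[p:p + H, p:p + W, p:p + Z]


class PointwiseConv3d(Module):
    """1x1x1 convolution: a channel-mixing matrix applied at every voxel."""

    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Parameter(_he_init(rng, (cin, cout), cin), "pconv.weight")
        self.bias = Parameter(np.zeros(cout), "pconv.bias") if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        y = np.tensordot(x, self.weight.data, axes=([3], [0]))
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, gy):
        x = self._x
        self.weight.grad += np.tensordot(x, gy, axes=([0, 1, 2], [0, 1, 2]))
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 1, 2))
        self._x = None
        return np.tensordot(gy, self.weight.data, axes=([3], [1]))


class TransposedConv3d(Module):
    """2x2x2 stride-2 transposed convolution (learnable upsampling)."""

    def __init__(self, cin: int, cout: int, kernel: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, kernel
        # stride == kernel: each output voxel receives exactly one tap
        self.weight = Parameter(_he_init(rng, (kernel ** 3, cin, cout), cin), "upconv.weight")
        self.bias = Parameter(np.zeros(cout), "upconv.bias")
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        H, W, Z, _ = x.shape
        k = self.k
        y = np.empty((H * k, W * k, Z * k, self.cout),
                     dtype=np.result_type(x.dtype, self.weight.data.dtype))
        for idx, (a, b, c) in enumerate(_offsets(k)):
            y[a::k, b::k, c::k] = np.tensordot(x, self.weight.data[idx], axes=([3], [0]))
        y += self.bias.data
        return y

    def backward(self, gy):
        x = self._x
        k = self.k
        gx = np.zeros_like(x)
        for idx, (a, b, c) in enumerate(_offsets(k)):
            g = gy[a::k, b::k, c::k]
            self.weight.grad[idx] += np.tensordot(x, g, axes=([0, 1, 2], [0, 1, 2]))
            gx += np.tensordot(g, self.weight.data[idx], axes=([3], [1]))
        self.bias.grad += gy.sum(axis=(0, 1, 2))
        self._x = None
        return gx


class MaxPool3d(Module):
    """2x2x2 max pooling; spatial dims must be even."""

    def __init__(self, kernel: int = 2):
        self.k = kernel
        self._cache: tuple | None = None

    def _window_view(self, x):
        H, W, Z, C = x.shape
        k = self.k
        xr = x.reshape(H // k, k, W // k, k, Z // k, k, C)
        return xr.transpose(0, 2, 4, 6, 1, 3, 5).reshape(
            H // k, W // k, Z // k, C, k ** 3
        )

    def forward(self, x, training=False):
        assert all(d % self.k == 0 for d in x.shape[:3]), x.shape
        xw = self._window_view(np.ascontiguousarray(x))
        arg = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (arg, x.shape)
        return y

    def backward(self, gy):
        arg, (H, W, Z, C) = self._cache
        k = self.k
        gw = np.zeros((H // k, W // k, Z // k, C, k ** 3), dtype=gy.dtype)
        np.put_along_axis(gw, arg[..., None], gy[..., None], axis=-1)
        gx = gw.reshape(H // k, W // k, Z // k, C, k, k, k)
        gx = gx.transpose(0, 4, 1, 5, 2, 6, 3).reshape(H, W, Z, C)
        self._cache = None
        return np.ascontiguousarray(gx)


class InstanceNorm3d(Module):
    """Per-channel normalization over the spatial extent, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), "in.gamma")
        self.beta = Parameter(np.zeros(channels), "in.beta")
        self._cache: tuple | None = None

    def forward(self, x, training=False):
        mu = x.mean(axis=(0, 1, 2), keepdims=True)
        var = x.var(axis=(0, 1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gy):
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.data
        m1 = gxhat.mean(axis=(0, 1, 2), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(0, 1, 2), keepdims=True)
        self._cache = None
        return (gxhat - m1 - xhat * m2) * inv


class ChannelLayerNorm(Module):
    """Layer norm across the channel axis at every voxel (transformer-style)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), "ln.gamma")
        self.beta = Parameter(np.zeros(channels), "ln.beta")
        self._cache: tuple | None = None

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gy):
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.data
        m1 = gxhat.mean(axis=-1, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
        self._cache = None
        return (gxhat - m1 - xhat * m2) * inv


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class Sigmoid(Module):
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, gy):
        y = self._y
        self._y = None
        return gy * y * (1.0 - y)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
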