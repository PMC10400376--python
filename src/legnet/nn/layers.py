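"""Minimal NumPy layer library with manual backpropagation.

Only what the sequence models here need: stride-1 'same'-padded 1D
convolutions (dense, grouped or depthwise), batch normalisation, SiLU,
sigmoid gates, linear and CP-factorized bilinear maps, global average
pooling and softmax-based losses. Tensors are (batch, channels, length)
float32 throughout. Each layer caches what its backward pass needs during
``forward(..., training=True)``; gradients accumulate into ``Param.grad``.

This exists because the execution environment provides no deep-learning
framework; the layer semantics intentionally mirror the common framework
conventions (BatchNorm eps 1e-5 / momentum 0.1, decoupled weight decay,
fan-out-scaled normal initialisation) so configurations are portable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "SiLU",
    "Identity",
    "Linear",
    "CPBilinear",
    "Sequential",
    "GlobalAvgPool",
    "softmax",
    "log_softmax",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name", "decay")

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = True):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.decay = decay  # decoupled weight decay applies only where True

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


def _fan_out_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape).astype(np.float32)


class Conv1d(Layer):
    """Stride-1 'same'-padded 1D convolution with optional channel groups.

    weight shape: (groups, out_per_group, in_per_group, kernel).
    ``groups=in_channels`` with one channel per group is a depthwise conv.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric 'same' padding")
        self.cin, self.cout, self.k, self.groups = in_channels, out_channels, kernel_size, groups
        self.cin_g = in_channels // groups
        self.cout_g = out_channels // groups
        rng = rng or np.random.default_rng(0)
        # EfficientNetV2-style init: normal with variance 2 / fan_out
        fan_out = self.cout_g * kernel_size
        w = _fan_out_normal(rng, (groups, self.cout_g, self.cin_g, kernel_size), fan_out)
        self.weight = Param(w, f"{name}.weight", decay=True)
        self.bias = Param(np.zeros(out_channels), f"{name}.bias", decay=False) if bias else None
        self._col: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (channels, batch, length) -> (out_channels, batch, length).

        Per kernel tap k this contracts the weight slice (g, out_g, in_g)
        with the contiguous padded activations (g, in_g, batch*length_pad)
        in a single batched GEMM, then accumulates the shifted slice into
        the output — no im2col materialisation.
        """
        c, b, L = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        if self.k == 1 and self.groups == 1:
            # pointwise fast path: one GEMM, no padding
            y = np.matmul(self.weight.value[0, :, :, 0], x.reshape(c, b * L))
            y = y.reshape(self.cout, b, L)
            if self.bias is not None:
                y += self.bias.value[:, None, None]
            if training:
                self._col = x
            return y
        p = (self.k - 1) // 2
        Lp = L + 2 * p
        g, cg, og = self.groups, self.cin_g, self.cout_g
        x_pad = np.empty((g, cg, b, Lp), dtype=np.float32)
        x_pad[:, :, :, :p] = 0.0
        x_pad[:, :, :, p + L :] = 0.0
        x_pad[:, :, :, p : p + L] = x.reshape(g, cg, b, L)
        flat = x_pad.reshape(g, cg, b * Lp)
        w = self.weight.value  # (g, og, cg, k)
        y = np.zeros((g, og, b, L), dtype=np.float32)
        z = np.empty((g, og, b * Lp), dtype=np.float32)
        for kk in range(self.k):
            np.matmul(np.ascontiguousarray(w[:, :, :, kk]), flat, out=z)
            y += z.reshape(g, og, b, Lp)[:, :, :, kk : kk + L]
        y = y.reshape(self.cout, b, L)
        if self.bias is not None:
            y += self.bias.value[:, None, None]
        if training:
            self._col = x_pad
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, b, L = dy.shape
        if self.k == 1 and self.groups == 1:
            x = self._col
            self._col = None
            dyf = dy.reshape(self.cout, b * L)
            xf = x.reshape(self.cin, b * L)
            self.weight.grad[0, :, :, 0] += np.matmul(dyf, xf.T)
            if self.bias is not None:
                self.bias.grad += dy.sum(axis=(1, 2))
            dx = np.matmul(self.weight.value[0, :, :, 0].T, dyf)
            return dx.reshape(self.cin, b, L)
        p = (self.k - 1) // 2
        Lp = L + 2 * p
        g, cg, og = self.groups, self.cin_g, self.cout_g
        x_pad = self._col
        self._col = None
        w = self.weight.value
        dyg = dy.reshape(g, og, b, L)
        dyf = dyg.reshape(g, og, b * L)
        # dw: correlation at each tap; padding margins are zero in dy_pad so
        # flattening (batch, length) into one axis cannot mix sequences
        dy_pad = np.zeros((g, og, b, Lp), dtype=np.float32)
        dy_pad[:, :, :, p : p + L] = dyg
        dypf = dy_pad.reshape(g, og, b * Lp)
        xf = x_pad.reshape(g, cg, b * Lp)
        T = b * Lp
        dw = self.weight.grad
        for kk in range(self.k):
            d = kk - p
            if d >= 0:
                a, xs = dypf[:, :, : T - d], xf[:, :, d:]
            else:
                a, xs = dypf[:, :, -d:], xf[:, :, : T + d]
            dw[:, :, :, kk] += np.matmul(a, xs.swapaxes(1, 2))
        # dx: transposed weights against dy, accumulated at shifted taps
        dx_pad = np.zeros((g, cg, b, Lp), dtype=np.float32)
        for kk in range(self.k):
            wt = np.ascontiguousarray(w[:, :, :, kk].swapaxes(1, 2))  # (g, cg, og)
            dx_pad[:, :, :, kk : kk + L] += np.matmul(wt, dyf).reshape(g, cg, b, L)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(1, 2))
        return dx_pad[:, :, :, p : p + L].reshape(self.cin, b, L)


class BatchNorm1d(Layer):
    """Per-channel batch normalisation; activations are (channels, b, L)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels), f"{name}.gamma", decay=False)
        self.beta = Param(np.zeros(channels), f"{name}.beta", decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            n = x.shape[1] * x.shape[2]
            mean = x.mean(axis=(1, 2))
            # one-pass second moment; cheaper than x.var's centred passes
            m2 = np.einsum("cbl,cbl->c", x, x, optimize=True) / n
            var = np.maximum(m2 - mean * mean, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = dy.shape[1] * dy.shape[2]
        dgamma = np.einsum("cbl,cbl->c", dy, xhat, optimize=True)
        dbeta = dy.sum(axis=(1, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[:, None, None]
        dx = (
            dy * g
            - (dbeta * self.gamma.value / n)[:, None, None]
            - xhat * ((dgamma * self.gamma.value / n)[:, None, None])
        ) * inv[:, None, None]
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class SiLU(Layer):
    """x * sigmoid(x)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = _sigmoid(x)
        if training:
            self._cache = (x, s)
        return x * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._cache
        self._cache = None
        return dy * (s * (1.0 + x * (1.0 - s)))


class Identity(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "linear",
    ):
        rng = rng or np.random.default_rng(0)
        # EfficientNetV2 linear init: uniform with range 1/sqrt(out_features)
        r = 1.0 / np.sqrt(out_features)
        w = rng.uniform(-r, r, size=(in_features, out_features)).astype(np.float32)
        self.weight = Param(w, f"{name}.weight", decay=True)
        self.bias = Param(np.zeros(out_features), f"{name}.bias", decay=False) if bias else None
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += x.T @ dy
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class CPBilinear(Layer):
    """Low-rank bilinear map h_j = sum_r U_jr (s . V_r)(s . W_r) [+ b_j].

    The dense bilinear weight tensor (out, in, in) is stored in canonical
    polyadic (rank-R) factor form: U (out, R), V (in, R), W (in, R), so the
    parameter count is R*(out + 2*in) instead of out*in*in.
    """

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rank: int,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "cpbilinear",
    ):
        if rank <= 0:
            raise ValueError("CP rank must be positive")
        rng = rng or np.random.default_rng(0)
        scale = (1.0 / (in_features * np.sqrt(rank))) ** 0.5
        self.U = Param(rng.normal(0, scale, (out_features, rank)).astype(np.float32), f"{name}.U")
        self.V = Param(rng.normal(0, scale, (in_features, rank)).astype(np.float32), f"{name}.V")
        self.W = Param(rng.normal(0, scale, (in_features, rank)).astype(np.float32), f"{name}.W")
        self.bias = Param(np.zeros(out_features), f"{name}.bias", decay=False) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        ps = [self.U, self.V, self.W]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def forward(self, s: np.ndarray, training: bool = False) -> np.ndarray:
        pv = s @ self.V.value  # (b, R)
        qw = s @ self.W.value  # (b, R)
        y = (pv * qw) @ self.U.value.T
        if self.bias is not None:
            y += self.bias.value
        if training:
            self._cache = (s, pv, qw)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, pv, qw = self._cache
        self._cache = None
        self.U.grad += dy.T @ (pv * qw)
        dprod = dy @ self.U.value  # (b, R)
        dpv = dprod * qw
        dqw = dprod * pv
        self.V.grad += s.T @ dpv
        self.W.grad += s.T @ dqw
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dpv @ self.V.value.T + dqw @ self.W.value.T

    def dense_parameter_count(self) -> int:
        out_f, _ = self.U.value.shape
        in_f, _ = self.V.value.shape
        return out_f * in_f * in_f + (out_f if self.bias is not None else 0)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class GlobalAvgPool(Layer):
    """Mean over the length axis: (c, b, L) -> (b, c)."""

    def __init__(self):
        self._L = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2).T

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self._L
        return np.repeat(dy.T[:, :, None] / L, L, axis=2).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))
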