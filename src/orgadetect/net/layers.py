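"""Differentiable numpy layers: conv (im2col+GEMM), batchnorm, activations,
upsample, concat, add. Each layer caches what its analytic backward needs;
`backward` returns one gradient per forward input and accumulates parameter
gradients in place."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ConvBNLeaky",
    "Upsample2x",
    "Concat",
    "Add",
    "im2col",
    "col2im",
    "sigmoid",
]

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    __slots__ = ("name", "data", "grad", "trainable")

    def __init__(self, data: np.ndarray, name: str = "", trainable: bool = True):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, *xs: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def col2im(
    dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int, ho: int, wo: int
) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        bias: bool = True,
        name: str = "conv",
        rng: np.random.Generator | None = None,
        bias_init: float = 0.0,
    ):
        rng = rng or np.random.default_rng(0)
        # He-style init for leaky-relu nets
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)), f"{name}.w")
        self.b = Param(np.full(cout, bias_init), f"{name}.b") if bias else None
        self.k, self.stride, self.pad = k, stride, k // 2
        self.name = name

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, ho, wo = im2col(x, self.k, self.stride, self.pad)
        cout = self.w.data.shape[0]
        y = np.matmul(self.w.data.reshape(cout, -1)[None], cols)
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(x.shape[0], cout, ho, wo)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        cols, x_shape, ho, wo = self._cache
        n, cout = grad.shape[:2]
        g = grad.reshape(n, cout, ho * wo)
        wf = self.w.data.reshape(cout, -1)
        self.w.grad += np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(wf.T[None], g)
        self._cache = None
        return (col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo),)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.name = name

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std) if train else None
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        xhat, inv_std = self._cache
        n, c, h, w = grad.shape
        m = n * h * w
        dg = (grad * xhat).sum(axis=(0, 2, 3))
        db = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dg
        self.beta.grad += db
        coeff = (self.gamma.data * inv_std)[None, :, None, None]
        dx = coeff * (grad - (db / m)[None, :, None, None] - xhat * (dg / m)[None, :, None, None])
        self._cache = None
        return (dx.astype(grad.dtype, copy=False),)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        g = np.where(self._neg, self.alpha * grad, grad)
        self._neg = None
        return (g,)


class ConvBNLeaky(Layer):
    """conv -> batchnorm -> leaky relu, the standard darknet block."""

    def __init__(self, cin, cout, k, stride=1, name="cbl", rng=None, alpha=0.1):
        self.conv = Conv2d(cin, cout, k, stride, bias=False, name=f"{name}.conv", rng=rng)
        self.bn = BatchNorm2d(cout, name=f"{name}.bn")
        self.act = LeakyReLU(alpha)
        self.name = name

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        (g,) = self.act.backward(grad)
        (g,) = self.bn.backward(g)
        return self.conv.backward(g)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        n, c, h, w = grad.shape
        return (grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)),)


class Concat(Layer):
    """Channel-axis concatenation of two maps."""

    def forward(self, a: np.ndarray, b: np.ndarray, train: bool = True) -> np.ndarray:
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        s = self._split
        return grad[:, :s], grad[:, s:]


class Add(Layer):
    """Residual addition."""

    def forward(self, a: np.ndarray, b: np.ndarray, train: bool = True) -> np.ndarray:
        return a + b

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        return grad, grad
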