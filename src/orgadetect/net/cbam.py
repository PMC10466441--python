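"""Convolutional block attention: channel attention then spatial attention.

Channel attention pools the feature map globally (average and max), pushes
both descriptors through one shared two-layer MLP (hidden size
``channels // reduction_ratio``, ReLU in between), sums the two outputs and
squashes with a logistic, giving one weight per channel in (0, 1). Spatial
attention stacks the channel-wise mean and max maps and convolves them with
a single odd-sized kernel (default 7x7), again logistic-squashed, giving one
weight per position. Each stage rescales the map it attended over; neither
changes its shape. ``bypass=True`` turns a block into the identity, which
recovers the plain (attention-free) network exactly.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, Layer, Param, sigmoid

__all__ = ["ChannelAttention", "SpatialAttention", "CBAM"]

F32 = np.float32


class ChannelAttention(Layer):
    def __init__(self, channels: int, reduction_ratio: int = 16, name: str = "ca", rng=None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction_ratio)
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        self.w1 = Param(rng.normal(0, s1, size=(hidden, channels)), f"{name}.w1")
        self.b1 = Param(np.zeros(hidden), f"{name}.b1")
        self.w2 = Param(rng.normal(0, s2, size=(channels, hidden)), f"{name}.w2")
        self.b2 = Param(np.zeros(channels), f"{name}.b2")
        self.name = name

    def params(self) -> list[Param]:
        return [self.w1, self.b1, self.w2, self.b2]

    def _mlp(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pre = d @ self.w1.data.T + self.b1.data
        h = np.maximum(pre, 0.0)
        return h @ self.w2.data.T + self.b2.data, pre

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention weights for a (N, C, H, W) map, in (0, 1)."""
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        sa, _ = self._mlp(avg)
        sm, _ = self._mlp(mx)
        return sigmoid(sa + sm)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        p = h * w
        flat = x.reshape(n, c, p)
        avg = flat.mean(axis=2)
        amax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        sa, pre_a = self._mlp(avg)
        sm, pre_m = self._mlp(mx)
        wgt = sigmoid(sa + sm)
        self._cache = (x, avg, mx, pre_a, pre_m, wgt, amax)
        return x * wgt[:, :, None, None]

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        x, avg, mx, pre_a, pre_m, wgt, amax = self._cache
        n, c, h, w = x.shape
        p = h * w
        dw = (grad * x).sum(axis=(2, 3))
        dx = grad * wgt[:, :, None, None]
        dlogit = dw * wgt * (1.0 - wgt)

        dpools = []
        for pooled, pre in ((avg, pre_a), (mx, pre_m)):
            dh = dlogit @ self.w2.data
            hid = np.maximum(pre, 0.0)
            self.w2.grad += dlogit.T @ hid
            self.b2.grad += dlogit.sum(axis=0)
            dpre = dh * (pre > 0)
            self.w1.grad += dpre.T @ pooled
            self.b1.grad += dpre.sum(axis=0)
            dpools.append(dpre @ self.w1.data)
        davg, dmax = dpools

        dx += davg[:, :, None, None] / p
        dxf = dx.reshape(n, c, p)
        np.put_along_axis(
            dxf, amax[:, :, None], np.take_along_axis(dxf, amax[:, :, None], axis=2) + dmax[:, :, None], axis=2
        )
        self._cache = None
        return (dxf.reshape(n, c, h, w),)


class SpatialAttention(Layer):
    def __init__(self, kernel_size: int = 7, name: str = "sa", rng=None):
        if kernel_size % 2 == 0:
            raise ValueError("spatial-attention kernel size must be odd")
        self.conv = Conv2d(2, 1, kernel_size, bias=True, name=f"{name}.conv", rng=rng)
        self.name = name

    def params(self) -> list[Param]:
        return self.conv.params()

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Per-position attention weights for a (N, C, H, W) map, in (0, 1)."""
        stacked = np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)
        return sigmoid(self.conv.forward(stacked, train=False))[:, 0]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        amax = x.argmax(axis=1)
        mx = np.take_along_axis(x, amax[:, None], axis=1)[:, 0]
        stacked = np.stack([x.mean(axis=1), mx], axis=1)
        logits = self.conv.forward(stacked, train)
        wgt = sigmoid(logits)
        self._cache = (x, wgt, amax)
        return x * wgt

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        x, wgt, amax = self._cache
        c = x.shape[1]
        dw = (grad * x).sum(axis=1, keepdims=True)
        dx = grad * wgt
        dlogits = dw * wgt * (1.0 - wgt)
        (dstacked,) = self.conv.backward(dlogits)
        dx += dstacked[:, 0:1] / c
        dmax = dstacked[:, 1]
        np.put_along_axis(
            dx, amax[:, None], np.take_along_axis(dx, amax[:, None], axis=1) + dmax[:, None], axis=1
        )
        self._cache = None
        return (dx,)


class CBAM(Layer):
    """Sequential channel then spatial attention; shape-preserving."""

    def __init__(self, channels: int, reduction_ratio: int = 16, kernel_size: int = 7,
                 name: str = "cbam", rng=None, bypass: bool = False):
        self.channel = ChannelAttention(channels, reduction_ratio, f"{name}.channel", rng)
        self.spatial = SpatialAttention(kernel_size, f"{name}.spatial", rng)
        self.bypass = bypass
        self.name = name

    def params(self) -> list[Param]:
        return self.channel.params() + self.spatial.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.bypass:
            return x
        return self.spatial.forward(self.channel.forward(x, train), train)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, ...]:
        if self.bypass:
            return (grad,)
        (g,) = self.spatial.backward(grad)
        return self.channel.backward(g)
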