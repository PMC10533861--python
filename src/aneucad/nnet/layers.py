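"""Numpy layers with manual backpropagation.

Conventions: activations are ``(N, C, H, W)`` float32 arrays; every layer
exposes ``forward(x, train)`` / ``backward(grad)`` and a ``params`` list
of :class:`Parameter` (value + accumulated gradient) for the optimizer.
"""

from __future__ import annotations

import numpy as np

#: working precision of the whole network
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Parameter",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "GlobalAvgPool2D",
    "Dense",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Conv2D:
    """k x k convolution, 'same'-style zero padding, optional stride.

    No bias term: every convolution is followed by batch normalization.
    Implemented as k*k shifted channel-mixing matmuls (one BLAS call per
    kernel tap), which avoids im2col gather/scatter entirely.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.weight = Parameter(w.astype(DTYPE), f"{name}.weight")
        self.params = [self.weight]
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def _out_hw(self, H: int, W: int) -> tuple[int, int]:
        Ho = (H + 2 * self.pad - self.k) // self.stride + 1
        Wo = (W + 2 * self.pad - self.k) // self.stride + 1
        return Ho, Wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        Ho, Wo = self._out_hw(H, W)
        s, k, p = self.stride, self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        taps = {}
        out = np.zeros((N, self.c_out, Ho * Wo), dtype=DTYPE)
        wv = self.weight.value
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, di : di + s * Ho : s, dj : dj + s * Wo : s]
                ).reshape(N, C, -1)
                taps[di, dj] = xs
                out += wv[:, :, di, dj] @ xs
        self._cache = (taps, xp.shape, (N, C, H, W), (Ho, Wo))
        return out.reshape(N, self.c_out, Ho, Wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        taps, xp_shape, (N, C, H, W), (Ho, Wo) = self._cache
        s, k, p = self.stride, self.k, self.pad
        g = grad.reshape(N, self.c_out, -1)
        wv = self.weight.value
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                xs = taps[di, dj]
                # (N,F,L) x (N,L,C) batched matmul summed over batch -> (F,C)
                self.weight.grad[:, :, di, dj] += (
                    g @ xs.transpose(0, 2, 1)
                ).sum(axis=0)
                dxs = (wv[:, :, di, dj].T @ g).reshape(N, C, Ho, Wo)
                dxp[:, :, di : di + s * Ho : s, dj : dj + s * Wo : s] += dxs
        if p:
            return dxp[:, :, p : p + H, p : p + W]
        return dxp


class BatchNorm2D:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE), f"{name}.beta")
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - gsum / m - xhat * gx_sum / m) * inv_std[None, :, None, None]
        return dx


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool2D:
    """Average pooling over the full spatial extent -> (N, C)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Dense:
    """Fully connected layer (N, C) -> (N, units)."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator | None = None,
                 name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / (c_in + units))
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(c_in, units)).astype(DTYPE), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(units, dtype=DTYPE), f"{name}.bias")
        self.params = [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T
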