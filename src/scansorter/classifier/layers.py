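"""Minimal NumPy neural-network layers for the slice classifier.

Only what the architecture needs: 2-D convolution (stride 1, 'same'
padding, im2col/GEMM), batch normalization, parametric ReLU, 2x2 max
pooling, average-pool input downsampling, flatten, dense, and a
concatenation point for the scalar 4-D label.  Every layer implements
``forward(x, training)`` and ``backward(grad, guided)``; in guided mode
each rectifier additionally zeroes negative gradients on the way back,
which is what turns a plain gradient map into a guided-backpropagation
saliency map.

All computation is float32.  There is no autograd: backward passes are
hand-derived, which keeps behaviour fully deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: parameter dict + cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError


class AvgPoolDown(Layer):
    """Non-learned average-pool downsampling of the input image.

    Reduced model configurations use this as their first layer so that a
    256x256 sample can be classified (and back-propagated through, for
    saliency) at a coarser working resolution.
    """

    def __init__(self, factor: int) -> None:
        super().__init__()
        if factor < 1:
            raise ValueError("downsample factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self.factor
        if f == 1:
            return x
        n, c, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"input size {h}x{w} not divisible by downsample factor {f}")
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        f = self.factor
        if f == 1:
            return grad
        g = np.repeat(np.repeat(grad, f, axis=2), f, axis=3)
        return (g / (f * f)).astype(np.float32)


class Conv2D(Layer):
    """3x3 (or kxk) convolution, stride 1, zero 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size ** 2
        fan_out = out_channels * kernel_size ** 2
        self.params["W"] = glorot_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, fan_out)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None
        #: set for the network's first convolution: its input gradient is
        #: never consumed during training (only saliency needs it, and the
        #: guided backward pass always computes it)
        self.skip_input_grad = False

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # (N, C, H, W, k, k) -> (N, H*W, C*k*k)
        view = sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        # reshape of the transposed view makes exactly one gather-copy
        return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"conv expected {self.in_channels} input channels, got {c}")
        cols = self._im2col(x.astype(np.float32))
        self._cols = cols
        self._in_shape = x.shape
        Wm = self.params["W"].reshape(self.out_channels, -1)
        y = cols @ Wm.T + self.params["b"]
        return y.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        n, _, h, w = self._in_shape
        g = grad.reshape(n, self.out_channels, h * w)
        cols = self._cols
        self.grads["W"] = np.einsum("nop,npi->oi", g, cols).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=(0, 2))
        if self.skip_input_grad and not guided:
            return np.zeros(self._in_shape, dtype=np.float32)
        # input gradient = correlation of grad with 180-degree-rotated,
        # channel-transposed kernels (exact for stride-1 'same' convolution)
        Wrot = self.params["W"].transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gcols = self._im2col(np.ascontiguousarray(grad, dtype=np.float32))
        gx = gcols @ Wrot.reshape(self.in_channels, -1).T
        return gx.transpose(0, 2, 1).reshape(self._in_shape).astype(np.float32)


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for conv input)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def _shape(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        if x.ndim == 4:
            return v.reshape(1, -1, 1, 1)
        return v.reshape(1, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv_std)
        self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32), axes, training)
        return (xhat * self._shape(x, self.params["gamma"]) + self._shape(x, self.params["beta"])).astype(np.float32)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        xhat, inv_std, axes, trained = self._cache
        g = self._shape(grad, self.params["gamma"])
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        if not trained:
            # inference-mode: running stats are constants, the map is affine
            return (grad * g * self._shape(grad, inv_std)).astype(np.float32)
        m = np.prod([grad.shape[a] for a in axes])
        gxhat = grad * g
        gx = (gxhat - gxhat.mean(axis=axes, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True))
        return (gx * self._shape(grad, inv_std)).astype(np.float32)


class PReLU(Layer):
    """Parametric ReLU with one learned slope per channel (init 0.25)."""

    def __init__(self, channels: int, init: float = 0.25) -> None:
        super().__init__()
        self.params["alpha"] = np.full(channels, init, dtype=np.float32)
        self._x: np.ndarray | None = None

    def _shape(self, x: np.ndarray) -> np.ndarray:
        a = self.params["alpha"]
        return a.reshape(1, -1, 1, 1) if x.ndim == 4 else a.reshape(1, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        neg = np.minimum(x, 0.0)
        self._neg = neg  # x on the negative part, 0 elsewhere
        return (np.maximum(x, 0.0) + self._shape(x) * neg).astype(np.float32)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        neg = self._neg
        axes = (0, 2, 3) if neg.ndim == 4 else (0,)
        self.grads["alpha"] = (grad * neg).sum(axis=axes)
        slope = np.where(neg < 0, self._shape(neg), 1.0)
        gx = grad * slope
        if guided:
            gx = np.maximum(gx, 0.0)  # guided backprop: drop negative gradients
        return gx.astype(np.float32)


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2.

    Tied maxima within a window (possible on flat regions) share the
    incoming gradient equally — a deterministic, symmetric convention.
    """

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.size
        n, c, h, w = x.shape
        if h % s or w % s:
            raise ValueError(f"pooling size {s} does not divide input {h}x{w}")
        windows = x.reshape(n, c, h // s, s, w // s, s)
        y = windows.max(axis=(3, 5))
        self._cache = (windows, y)
        return y

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        windows, y = self._cache
        n, c, h2, s, w2, _ = windows.shape
        mask = (windows == y[:, :, :, None, :, None])
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None] / counts)
        return g.reshape(n, c, h2 * s, w2 * s).astype(np.float32)


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (in_features, out_features),
                                          in_features, out_features)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return (x @ self.params["W"] + self.params["b"]).astype(np.float32)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return (grad @ self.params["W"].T).astype(np.float32)


class ConcatScalar(Layer):
    """Append one scalar feature (the 4-D label) to a flat feature vector."""

    def __init__(self) -> None:
        super().__init__()
        self.scalar: np.ndarray | None = None  # set by the network before forward

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.scalar is None:
            raise ValueError("ConcatScalar.scalar not set")
        s = np.asarray(self.scalar, dtype=np.float32).reshape(-1, 1)
        if s.shape[0] != x.shape[0]:
            raise ValueError("4-D label batch size mismatch")
        return np.concatenate([x, s], axis=1)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        return grad[:, :-1]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), labels] + eps).mean())
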