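"""Minimal NumPy neural-network layers with hand-derived backward passes.

The simulation needs full control over individual weights (pinning ablated
entries to exactly zero after every optimizer step), so the network is built
on plain NumPy arrays rather than an autodiff framework.  Layers follow the
usual convention: ``forward(x, training)`` caches what ``backward(grad)``
needs; parameters and their gradients live in ``params`` / ``grads`` dicts
keyed by short names (``"W"``, ``"b"``, ``"gamma"``, ``"beta"``).

All convolutions are stride-1 with symmetric zero padding; spatial
downsampling is done by 2x2 max pooling, which matches VGG-style blocks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: a named, optionally parameterized, differentiable op."""

    #: layers whose ``params["W"]`` is an ablatable multiplicative weight tensor
    has_weight = False

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, input_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Shape of one sample's output given one sample's input shape."""
        raise NotImplementedError

    # -- state ----------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            np.copyto(self.params[k], v)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.name!r})"


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) via im2col + GEMM."""

    has_weight = True

    def __init__(self, name, in_channels, out_channels, kernel_size=3, padding=1,
                 rng=None, dtype=np.float32):
        super().__init__(name)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.params["W"] = _he_normal(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype
        )
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._cache = None

    def output_shape(self, input_shape):
        c, h, w = input_shape
        k, p = self.kernel_size, self.padding
        return (self.out_channels, h + 2 * p - k + 1, w + 2 * p - k + 1)

    @staticmethod
    def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
        # xp: (N, C, Hp, Wp) -> (C*k*k, N*Hout*Wout), columns ordered N-major
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(1, 4, 5, 0, 2, 3)
        return np.ascontiguousarray(cols).reshape(xp.shape[1] * k * k, -1)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"{self.name}: expected {self.in_channels} input channels, got {c}"
            )
        k, p = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        hout, wout = h + 2 * p - k + 1, w + 2 * p - k + 1
        cols = self._im2col(xp, k)
        w_mat = self.params["W"].reshape(self.out_channels, -1)
        out = w_mat @ cols + self.params["b"][:, None]
        out = out.reshape(self.out_channels, n, hout, wout).transpose(1, 0, 2, 3)
        if training:
            self._cache = (cols, x.shape, (hout, wout))
        return np.ascontiguousarray(out)

    def backward(self, grad):
        cols, x_shape, (hout, wout) = self._cache
        n, c, h, w = x_shape
        k, p = self.kernel_size, self.padding
        g_mat = np.ascontiguousarray(grad.transpose(1, 0, 2, 3)).reshape(
            self.out_channels, -1
        )
        self.grads["W"] = (g_mat @ cols.T).reshape(self.params["W"].shape)
        self.grads["b"] = g_mat.sum(axis=1)
        dcols = self.params["W"].reshape(self.out_channels, -1).T @ g_mat
        dcols = dcols.reshape(c, k, k, n, hout, wout)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + hout, j : j + wout] += dcols[:, i, j].transpose(
                    1, 0, 2, 3
                )
        self._cache = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training uses batch mean/variance (biased) and updates running stats with
    momentum 0.1; evaluation always uses the running stats, which keeps
    accuracy and activation readouts deterministic for fixed weights.
    """

    def __init__(self, name, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__(name)
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def output_shape(self, input_shape):
        return input_shape

    def forward(self, x, training=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return g * xhat + b

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g = self.params["gamma"][None, :, None, None]
        dxhat = grad * g
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = inv_std[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx.astype(grad.dtype)

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        state = dict(state)
        self.running_mean = state.pop("running_mean").copy()
        self.running_var = state.pop("running_var").copy()
        super().load_state(state)


class ReLU(Layer):
    def __init__(self, name):
        super().__init__(name)
        self._mask = None

    def output_shape(self, input_shape):
        return input_shape

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2 (input spatial dims must be even)."""

    def __init__(self, name):
        super().__init__(name)
        self._cache = None

    def output_shape(self, input_shape):
        c, h, w = input_shape
        if h % 2 or w % 2:
            raise ValueError(f"{self.name}: odd spatial size {h}x{w} cannot be pooled")
        return (c, h // 2, w // 2)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad):
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class Flatten(Layer):
    def __init__(self, name):
        super().__init__(name)
        self._shape = None

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    has_weight = True

    def __init__(self, name, in_features, out_features, rng=None, dtype=np.float32):
        super().__init__(name)
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _he_normal(rng, (out_features, in_features), in_features, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)
        self._x = None

    def output_shape(self, input_shape):
        (f,) = input_shape
        if f != self.in_features:
            raise ValueError(
                f"{self.name}: expected {self.in_features} input features, got {f}"
            )
        return (self.out_features,)

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        dx = grad @ self.params["W"]
        self._x = None
        return dx


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    Returns ``(loss, dlogits, probs)``; the gradient already carries the 1/N
    factor so it can be fed straight into ``backward``.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(logits.dtype), probs
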