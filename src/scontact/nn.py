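"""Minimal numpy neural-network primitives for the convolutional ecDNA
caller: width-wise convolution, batch normalisation, ReLU/GELU, max
pooling, dropout, dense layers, the AdamW optimiser and the hard
bootstrapped cross-entropy loss.

Everything is deterministic given a single ``numpy.random.Generator``:
weight initialisation, mini-batch shuffling and dropout masks all draw
from it in a fixed order, so training trajectories are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "ConvWidth",
    "BatchNorm",
    "ReLU",
    "GELU",
    "MaxPoolWidth",
    "Dropout",
    "Dense",
    "AdamW",
    "softmax",
    "bootstrapped_cross_entropy",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Layer:
    """Base layer: trainable ``params``/``grads`` dicts and a
    ``decay`` set naming the parameters subject to weight decay."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.decay: set[str] = set()

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ConvWidth(Layer):
    """Convolution scanning along the width of an (N, C, H, W) input
    with a full-height kernel, collapsing H to 1.

    Kernel (H, kw), stride 1, zero padding of ``pad`` columns on each
    side.  Output is (N, out_ch, W + 2*pad - kw + 1).  A 1-D conv over
    an (N, C, W) input is the ``height=1`` special case.
    """

    def __init__(self, in_ch: int, height: int, out_ch: int, kw: int, pad: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.height, self.kw, self.pad = in_ch, height, kw, pad
        fan_in = in_ch * height * kw
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch * height, kw))
        self.params["b"] = np.zeros(out_ch)
        self.decay = {"W"}

    def forward(self, x, train, rng):
        self._flat_input = x.ndim == 3
        if self._flat_input:  # (N, C, W) -> height 1
            x = x[:, :, None, :]
        n, c, h, w = x.shape
        xr = x.reshape(n, c * h, w)
        xp = np.pad(xr, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kw, axis=2)
        self._cache = (win, (n, c, h, w))
        out = np.einsum("ncwk,fck->nfw", win, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        win, (n, c, h, w) = self._cache
        self.grads["W"] = np.einsum("ncwk,nfw->fck", win, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        w_out = dout.shape[2]
        dxp = np.zeros((n, c * h, w + 2 * self.pad))
        wt = self.params["W"]
        for k in range(self.kw):
            dxp[:, :, k : k + w_out] += np.einsum(
                "nfw,fc->ncw", dout, wt[:, :, k], optimize=True
            )
        dx = dxp[:, :, self.pad : self.pad + w] if self.pad else dxp
        return dx.reshape(n, c, w) if self._flat_input else dx.reshape(n, c, h, w)


class BatchNorm(Layer):
    """Batch normalisation over all axes except the channel axis.

    ``n_features`` channels on ``channel_axis`` (1 for conv activations
    (N, C, W), -1 for dense activations (N, D)).  Batch statistics in
    training; running averages (momentum 0.1) in evaluation.
    """

    def __init__(self, n_features: int, channel_axis: int = 1,
                 eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.axis = channel_axis
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[self.axis] = x.shape[self.axis]
        return tuple(shape)

    def forward(self, x, train, rng):
        axes = tuple(i for i in range(x.ndim) if i != self.axis % x.ndim)
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) / std.reshape(sh)
        self._cache = (xhat, std, axes, sh, train)
        return self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)

    def backward(self, dout):
        xhat, std, axes, sh, train = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(sh)
        if not train:
            return dout * g / std.reshape(sh)
        m = np.prod([xhat.shape[a] for a in axes])
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        ) / std.reshape(sh)
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class GELU(Layer):
    """Exact Gaussian error linear unit: ``x * Phi(x)``."""

    def forward(self, x, train, rng):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._cdf

    def backward(self, dout):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * self._x**2)
        return dout * (self._cdf + self._x * pdf)


class MaxPoolWidth(Layer):
    """Max pooling along the last axis (width), default window 2."""

    def __init__(self, window: int = 2) -> None:
        super().__init__()
        self.window = window

    def forward(self, x, train, rng):
        n, c, w = x.shape
        if w % self.window:
            raise ValueError(f"width {w} not divisible by pool window {self.window}")
        xr = x.reshape(n, c, w // self.window, self.window)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        n, c, wo = dout.shape
        dx = np.zeros((n, c, wo, self.window))
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=3)
        return dx.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), (out_dim, in_dim))
        self.params["b"] = np.zeros(out_dim)
        self.decay = {"W"}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class AdamW(Layer):
    """AdamW: Adam with decoupled weight decay (applied to weight
    matrices, not biases or batch-norm affine parameters)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, weight_decay: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                v = self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                if k in layer.decay and self.wd:
                    p -= self.lr * self.wd * p
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bootstrapped_cross_entropy(
    logits: np.ndarray,
    y: np.ndarray,
    beta: float = 0.99,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Hard bootstrapped cross-entropy with per-class weights.

    The target mixes the one-hot truth ``t`` with the one-hot argmax
    prediction ``z``: ``L = -sum_c (beta*t_c + (1-beta)*z_c) log p_c``,
    averaged with weights taken from the true class.  At ``beta = 1``
    (and unit weights) this is exactly the cross-entropy.

    Returns ``(loss, dlogits, probs)``; the bootstrap target is treated
    as a constant in the gradient.
    """
    n, k = logits.shape
    p = softmax(logits)
    t = np.zeros((n, k))
    t[np.arange(n), y] = 1.0
    z = np.zeros((n, k))
    z[np.arange(n), p.argmax(axis=1)] = 1.0
    q = beta * t + (1.0 - beta) * z
    w = np.ones(n) if class_weights is None else np.asarray(class_weights, float)[y]
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(w * (q * logp).sum(axis=1)).sum() / w.sum())
    dlogits = (w[:, None] * (q.sum(axis=1, keepdims=True) * p - q)) / w.sum()
    return loss, dlogits, p
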