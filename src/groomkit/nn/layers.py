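"""Minimal NumPy neural-network layers with explicit backpropagation.

The classifier at the heart of this package is small (tens of thousands of
parameters) and trained on short synthetic or pre-extracted clip samples, so
the layers are implemented directly on NumPy arrays in float64.  Every layer
follows the same protocol:

* ``forward(x, train=False)`` returns the output and stashes whatever the
  backward pass needs;
* ``backward(dout)`` returns the gradient w.r.t. the input and accumulates
  parameter gradients into ``Param.grad``;
* ``params()`` lists the layer's :class:`Param` objects.

Gradients of parameters whose ``trainable`` flag is off are never
accumulated: after ``zero_grad`` they stay identically zero, which makes
freeze/finetune audits trivial.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "BatchNorm1d",
    "LSTM",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A named tensor with gradient storage and a trainable flag."""

    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# convolution helpers (im2col / col2im)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (B, C, Ho, Wo, k, k) -> (B, C*k*k, Ho*Wo)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - k + 1, wp - k + 1
    dcols = dcols.reshape(b, c, k, k, ho, wo)
    dxp = np.zeros((b, c, hp, wp))
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """3x3-style same convolution, stride 1, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int,
                 rng: np.random.Generator, name: str):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, scale, (out_ch, in_ch * kernel * kernel)),
                       f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self.kernel = kernel
        self.pad = pad
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"{self.W.name}: expected {self.in_ch} input channels, got {x.shape[1]}")
        cols = _im2col(x, self.kernel, self.pad)
        ho = x.shape[2] + 2 * self.pad - self.kernel + 1
        wo = x.shape[3] + 2 * self.pad - self.kernel + 1
        out = np.einsum("oc,bcl->bol", self.W.value, cols, optimize=True)
        out += self.b.value[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        b = dout.shape[0]
        dflat = dout.reshape(b, self.out_ch, -1)
        if self.W.trainable:
            self.W.grad += np.einsum("bol,bcl->oc", dflat, cols, optimize=True)
        if self.b.trainable:
            self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.W.value, dflat, optimize=True)
        return _col2im(dcols, x_shape, self.kernel, self.pad)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(b, c, h, w)


class GlobalAvgPool(Layer):
    """Mean over the spatial dims: (B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._x_shape).copy()


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._x_shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / in_dim)
        self.W = Param(rng.normal(0.0, scale, (out_dim, in_dim)), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.W.trainable:
            self.W.grad += dout.T @ self._x
        if self.b.trainable:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class BatchNorm1d(Layer):
    """Batch normalisation over a (B, D) tensor with running statistics."""

    def __init__(self, dim: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim), f"{name}.gamma")
        self.beta = Param(np.zeros(dim), f"{name}.beta")
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, n = self._cache
        if self.gamma.trainable:
            self.gamma.grad += (dout * xhat).sum(axis=0)
        if self.beta.trainable:
            self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv_std
        # standard batch-norm backward through the batch statistics
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class LSTM(Layer):
    """Single-layer LSTM consuming (B, T, D); returns the final hidden state h_T.

    tanh cell/output activations, sigmoid gates, forget-gate bias initialised
    to 1.  The final hidden state is the clip-level summary used downstream.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, name: str):
        self.hidden = hidden
        scale_x = np.sqrt(1.0 / in_dim)
        scale_h = np.sqrt(1.0 / hidden)
        self.Wx = Param(rng.normal(0.0, scale_x, (4 * hidden, in_dim)), f"{name}.Wx")
        self.Wh = Param(rng.normal(0.0, scale_h, (4 * hidden, hidden)), f"{name}.Wh")
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget gate bias
        self.b = Param(b, f"{name}.b")

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        caches = []
        for step in range(t):
            xt = x[:, step, :]
            a = xt @ self.Wx.value.T + h @ self.Wh.value.T + self.b.value
            i = _sigmoid(a[:, :hdim])
            f = _sigmoid(a[:, hdim : 2 * hdim])
            g = np.tanh(a[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(a[:, 3 * hdim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((xt, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        self._caches = caches
        self._x_shape = x.shape
        return h

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        b, t, d = self._x_shape
        hdim = self.hidden
        dx = np.zeros((b, t, d))
        dh = dh_final
        dc = np.zeros((b, hdim))
        dWx = np.zeros_like(self.Wx.value)
        dWh = np.zeros_like(self.Wh.value)
        db = np.zeros_like(self.b.value)
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._caches[step]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += da.T @ xt
            dWh += da.T @ h_prev
            db += da.sum(axis=0)
            dx[:, step, :] = da @ self.Wx.value
            dh = da @ self.Wh.value
            dc = dc * f
        if self.Wx.trainable:
            self.Wx.grad += dWx
        if self.Wh.trainable:
            self.Wh.grad += dWh
        if self.b.trainable:
            self.b.grad += db
        return dx
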