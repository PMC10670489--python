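"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the CNN-LSTM classifier needs: stride-1 'same' 2-D convolution,
ReLU, 2x2 max pooling, inverted dropout, flatten, dense, and an LSTM whose
output is its last hidden state.  Every layer exposes ``params``/``grads``
(parallel lists of arrays) plus ``forward(x, train)`` / ``backward(dy)``.
Gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "ReLU", "MaxPool2D", "Dropout", "Flatten",
    "Dense", "LSTM", "sigmoid", "softmax", "Adam",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution (cross-correlation), He-initialized."""

    def __init__(self, in_channels: int, filters: int, kh: int, kw: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (in_channels * kh * kw))
        self.W = rng.normal(0.0, scale, size=(filters, in_channels, kh, kw))
        self.b = np.zeros(filters)
        self.kh, self.kw = kh, kw
        # asymmetric 'same' padding for even kernels
        self.pt, self.pl = (kh - 1) // 2, (kw - 1) // 2
        self.pb, self.pr = kh - 1 - self.pt, kw - 1 - self.pl
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pt, self.pb), (self.pl, self.pr)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        self._win = win  # (N, C, H, W, kh, kw)
        return np.einsum("nchwuv,fcuv->nfhw", win, self.W, optimize=True) \
            + self.b[None, :, None, None]

    def backward(self, dy):
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        self.grads[0][...] = np.einsum("nfhw,nchwuv->fcuv", dy, self._win,
                                       optimize=True)
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.pb, self.pt), (self.pr, self.pl)))
        win = sliding_window_view(dyp, (self.kh, self.kw), axis=(2, 3))
        Wf = self.W[:, :, ::-1, ::-1]
        return np.einsum("nfhwuv,fcuv->nchw", win, Wf, optimize=True)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling (floor semantics); degenerate dims of size 1 pass
    through so very deep stacks on small maps remain valid."""

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        ph, pw = (2 if H >= 2 else 1), (2 if W >= 2 else 1)
        Hc, Wc = (H // ph) * ph, (W // pw) * pw
        self._shape, self._ph, self._pw = x.shape, ph, pw
        xc = x[:, :, :Hc, :Wc]
        xr = xc.reshape(N, C, Hc // ph, ph, Wc // pw, pw) \
               .transpose(0, 1, 2, 4, 3, 5) \
               .reshape(N, C, Hc // ph, Wc // pw, ph * pw)
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._shape
        ph, pw = self._ph, self._pw
        Ho, Wo = dy.shape[2], dy.shape[3]
        flat = np.zeros((N, C, Ho, Wo, ph * pw))
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros((N, C, H, W))
        block = flat.reshape(N, C, Ho, Wo, ph, pw).transpose(0, 1, 2, 4, 3, 5) \
                    .reshape(N, C, Ho * ph, Wo * pw)
        dx[:, :, : Ho * ph, : Wo * pw] = block
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class LSTM(Layer):
    """Single LSTM layer over a short slice sequence; returns the final
    hidden state.  Gate order: input, forget, cell, output."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(n_in + units)
        self.Wx = rng.normal(0.0, scale, size=(n_in, 4 * units))
        self.Wh = rng.normal(0.0, scale, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.units = units
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        N, T, D = x.shape
        H = self.units
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last):
        x = self._x
        N, T, D = x.shape
        H = self.units
        dx = np.zeros_like(x)
        for grad in self.grads:
            grad[...] = 0.0
        dh = dh_last
        dc = np.zeros((N, H))
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, c_new = self._cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += x[:, t].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
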