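"""Minimal feed-forward network engine (numpy, float32).

The two architectures in this package are small and fixed — a LeNet-style
patch classifier and a four-layer fully convolutional segmenter — so this
module provides exactly the pieces they need: 3x3 "same" convolutions via
im2col, ReLU, 2x2 max pooling, dense layers, softmax utilities, and Adam.
Layers expose ``forward``/``backward`` and carry their parameters and
gradients; :class:`Sequential` chains them.  All arrays are float32 in
(N, C, H, W) layout.

Everything is deterministic given the ``numpy.random.Generator`` used for
initialization and batch shuffling.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        k = 3
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.weight = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(F32)
        self.bias = np.zeros(c_out, dtype=F32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3) -> cols (N*H*W, C*9)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * 9)
        cols = np.ascontiguousarray(cols, dtype=F32)
        out = cols @ self.weight.T + self.bias
        self._cols = cols
        self._shape = (N, C, H, W)
        return out.reshape(N, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(N * H * W, -1).astype(F32)
        self.grads[0][...] = dmat.T @ self._cols
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = dmat @ self.weight  # (N*H*W, C*9)
        dcols = dcols.reshape(N, H, W, C, 3, 3)
        dxp = np.zeros((N, C, H + 2, W + 2), dtype=F32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + H, dj : dj + W] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, 1 : 1 + H, 1 : 1 + W]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return xr.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=F32)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(N, C, H, W)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.weight = (rng.standard_normal((d_out, d_in)) * scale).astype(F32)
        self.bias = np.zeros(d_out, dtype=F32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(F32)
        return self._x @ self.weight.T + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(F32)
        self.grads[0][...] = dout.T @ self._x
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.weight


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient through a softmax: rows of ``probs`` on the simplex,
    ``dprobs`` = dL/dp; returns dL/dlogits (last axis is the class axis)."""
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - dot)
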