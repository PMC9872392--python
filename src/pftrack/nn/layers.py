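"""Minimal CNN layers (forward + backprop) in numpy, NHWC layout.

Only what a small U-Net needs: 3x3/1x1 'same' convolutions via im2col + GEMM,
2x2 max-pooling, 2x2-stride-2 transposed convolutions, ReLU. NHWC keeps the
im2col gather channel-contiguous, which is what makes CPU training viable.
Each layer caches what its backward pass needs; `params()` exposes
(array, grad) pairs for the optimizer. Arrays are float32 by default; any
float dtype flows through unchanged (float64 is used by the gradient checks).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype=DTYPE) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d:
    """k x k convolution (k = 3 or 1), stride 1, 'same' zero padding.

    Weights (k, k, C_in, C_out). The 3x3 case runs through direct numba
    kernels; 1x1 is a plain GEMM.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=DTYPE):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = _he_init(rng, (k, k, c_in, c_out), fan_in=c_in * k * k, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        from ._kernels import conv3x3_fwd

        n, h, w, c = x.shape
        if self.k == 1:
            xf = np.ascontiguousarray(x).reshape(-1, c)
            if train:
                self._xpad, self._shape = xf, x.shape
            y = xf @ self.w.reshape(c, self.c_out) + self.b
            return y.reshape(n, h, w, self.c_out)
        xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if train:
            self._xpad, self._shape = xpad, x.shape
        return conv3x3_fwd(xpad, self.w, self.b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        from ._kernels import conv3x3_bwd

        n, h, w, c = self._shape
        if self.k == 1:
            dyf = np.ascontiguousarray(dy).reshape(-1, self.c_out)
            self.dw += (self._xpad.T @ dyf).reshape(self.w.shape)
            self.db += dyf.sum(axis=0)
            dx = dyf @ self.w.reshape(c, self.c_out).T
            self._xpad = None
            return dx.reshape(n, h, w, c)
        dy = np.ascontiguousarray(dy)
        dxpad, dw, db = conv3x3_bwd(self._xpad, self.w, dy)
        self.dw += dw
        self.db += db
        self._xpad = None
        return np.ascontiguousarray(dxpad[:, 1:1 + h, 1:1 + w, :])

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []

    n_params = 0


class MaxPool2:
    """2x2 max pooling, stride 2; input H, W must be even.

    Backward routes the gradient to exactly one pixel per window (first of the
    four quadrant slices to attain the maximum), so tied maxima are not
    double-counted.
    """

    def __init__(self):
        self._masks = None
        self._shape = None

    @staticmethod
    def _slices(x):
        return (x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
                x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self._slices(x)
        y = np.maximum(np.maximum(s[0], s[1]), np.maximum(s[2], s[3]))
        if train:
            masks = []
            taken = np.zeros(y.shape, dtype=bool)
            for q in s:
                m = (q == y) & ~taken
                taken |= m
                masks.append(m)
            self._masks, self._shape = masks, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        for q, m in zip(self._slices(dx), self._masks):
            q[m] = dy[m]
        self._masks = None
        return dx

    def params(self):
        return []

    n_params = 0


class ConvTranspose2:
    """2x2 transposed convolution with stride 2 (learned 2x upsampling).

    Weights (2, 2, C_in, C_out): output quadrant (a, b) is x @ w[a, b].
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=DTYPE):
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, (2, 2, c_in, c_out), fan_in=c_in, dtype=dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xf = x.reshape(-1, c)
        y = np.empty((n, 2 * h, 2 * w, self.c_out), dtype=x.dtype)
        for a in range(2):
            for b in range(2):
                y[:, a::2, b::2, :] = (xf @ self.w[a, b] + self.b).reshape(n, h, w, self.c_out)
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x.shape
        xf = self._x.reshape(-1, c)
        dx = np.zeros((n * h * w, c), dtype=dy.dtype)
        for a in range(2):
            for b in range(2):
                dq = np.ascontiguousarray(dy[:, a::2, b::2, :]).reshape(-1, self.c_out)
                self.dw[a, b] += xf.T @ dq
                self.db += dq.sum(axis=0)
                dx += dq @ self.w[a, b].T
        self._x = None
        return dx.reshape(n, h, w, c)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz, prob)."""
    p = sigmoid(z)
    # max(z,0) - z*t + log(1+e^-|z|) is stable for float32 logits
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    dz = ((p - target) / z.size).astype(z.dtype)
    return float(loss.mean()), dz, p


class Adam:
    """Adam optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0
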