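"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly the operations a nested-skip encoder-decoder segmenter
needs -- 3x3/1x1 convolution, batch normalization, ReLU, 2x2 max pooling,
2x nearest-neighbour upsampling -- plus the Adam optimizer. Layouts are
channels-last: activations are float32 arrays of shape (N, H, W, C).

Convolutions are computed as nine shifted (N*H*W, Cin) @ (Cin, Cout) matrix
products so that both the forward and backward passes run through BLAS
without materializing an im2col buffer. Each layer instance caches what its
backward pass needs; a layer is used at most once per forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; subclasses define forward/backward and expose parameters
    as (value, gradient) pairs for the optimizer."""

    def params(self):
        return []

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0


class Conv3x3(Layer):
    """3x3 convolution, stride 1, 'same' zero padding.

    Computed as nine (N*H*W, Cin) @ (Cin, Cout) matrix products taken
    directly on the contiguous input, scatter-added into a zero-padded
    output accumulator (forward), and nine cheap Cout-channel window reads
    of the padded output gradient (backward). This keeps all heavy data
    motion inside BLAS: no im2col buffer and no wide-channel patch copies
    are ever materialized.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        # He initialization for ReLU networks
        std = np.sqrt(2.0 / (9 * cin))
        self.W = rng.normal(0.0, std, (3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x
        N, H, W, cin = x.shape
        cout = self.W.shape[3]
        x_flat = x.reshape(-1, cin)
        # accumulate into a padded buffer: the (dy, dx) product lands shifted
        # by (1-dy, 1-dx); border contributions fall outside and are dropped
        acc3 = np.zeros((N, H + 2, (W + 2) * cout), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                t = (x_flat @ self.W[dy, dx]).reshape(N, H, W * cout)
                acc3[:, 2 - dy : H + 2 - dy, (2 - dx) * cout : (2 - dx + W) * cout] += t
        acc = acc3.reshape(N, H + 2, W + 2, cout)
        return np.ascontiguousarray(acc[:, 1:-1, 1:-1, :]) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        N, H, W, cin = x.shape
        cout = dout.shape[3]
        x_flat = x.reshape(-1, cin)
        flat_dout = np.ascontiguousarray(dout.reshape(-1, cout))
        self.db += flat_dout.sum(axis=0)
        dpad = np.zeros((N, H + 2, W + 2, cout), dtype=np.float32)
        dpad[:, 1:-1, 1:-1, :] = dout
        dpad3 = dpad.reshape(N, H + 2, (W + 2) * cout)
        dx_flat = np.zeros((N * H * W, cin), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                band = dpad3[:, 2 - dy : H + 2 - dy, (2 - dx) * cout : (2 - dx + W) * cout]
                d_win = np.ascontiguousarray(band).reshape(-1, cout)
                self.dW[dy, dx] += x_flat.T @ d_win
                dx_flat += d_win @ self.W[dy, dx].T
        return dx_flat.reshape(N, H, W, cin)


class Conv1x1(Layer):
    """1x1 convolution (per-pixel linear map); used for output heads."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            self.W = np.zeros((cin, cout), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / cin)
            self.W = rng.normal(0.0, std, (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cin, cout = self.W.shape
        flat_x = self._x.reshape(-1, cin)
        flat_d = dout.reshape(-1, cout)
        self.dW += flat_x.T @ flat_d
        self.db += flat_d.sum(axis=0)
        self._x = None
        return (flat_d @ self.W.T).reshape(self._shape_like(dout, cin))

    @staticmethod
    def _shape_like(dout, cin):
        return dout.shape[:-1] + (cin,)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = (0, 1, 2)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._cache = (xhat, invstd.astype(np.float32))
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        m = float(np.prod(dout.shape[:3]))
        sum_d = dout.sum(axis=(0, 1, 2))
        sum_dx = (dout * xhat).sum(axis=(0, 1, 2))
        self.dgamma += sum_dx
        self.dbeta += sum_d
        dx = (self.gamma * invstd / m) * (m * dout - sum_d - xhat * sum_dx)
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dout, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input H and W must be even."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, H, W, C = x.shape
        self._shape = x.shape
        blocks = x.reshape(N, H // 2, 2, W // 2, 2, C)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
        self._argmax = blocks.argmax(axis=4)
        return np.take_along_axis(blocks, self._argmax[..., None], axis=4)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, H, W, C = self._shape
        blocks = np.zeros((N, H // 2, W // 2, C, 4), dtype=np.float32)
        np.put_along_axis(blocks, self._argmax[..., None], dout[..., None], axis=4)
        self._argmax = None
        dx = blocks.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(N, H, W, C)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, H, W, C = dout.shape
        return dout.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Adam:
    """Adam optimizer over a list of (value, gradient) array pairs."""

    def __init__(self, param_pairs, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_pairs)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
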