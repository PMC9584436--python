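"""Minimal numpy neural-network layers with hand-written backpropagation.

Only what the two pipeline networks need: 2D convolutions (im2col), residual
blocks, batch normalization, fully connected layers, ReLU, global average
pooling, SGD with warm restarts + cosine annealing, and Adam.  All layers are
deterministic given the initialization RNG; inference is stateless.
"""

from __future__ import annotations

import math

import numpy as np


class Layer:
    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (b, c, ho, wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo, xp.shape)


def _col2im(dcols, k, stride, pad, ho, wo, xp_shape):
    b, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, fan_in)) * math.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def forward(self, x, train=False):
        cols, (ho, wo, xp_shape) = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (cols, ho, wo, xp_shape, x.shape[0])
        out = cols @ self.W.T + self.b  # (b, ho*wo, cout)
        return out.transpose(0, 2, 1).reshape(x.shape[0], -1, ho, wo)

    def backward(self, grad):
        cols, ho, wo, xp_shape, b = self._cache
        g = grad.reshape(b, -1, ho * wo).transpose(0, 2, 1)  # (b, ho*wo, cout)
        self.dW += np.einsum("bpc,bpk->ck", g, cols, optimize=True)
        self.db += g.sum(axis=(0, 1))
        dcols = g @ self.W
        return _col2im(dcols, self.k, self.stride, self.pad, ho, wo, xp_shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((cin, cout)) * math.sqrt(2.0 / cin)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm1d(Layer):
    def __init__(self, n, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(n, dtype=np.float32)
        self.beta = np.zeros(n, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._xhat = (x - mu) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat, istd = self._xhat, self._istd
        self.dgamma += (grad * xhat).sum(axis=0)
        self.dbeta += grad.sum(axis=0)
        if not self._train:
            return grad * self.gamma * istd
        n = grad.shape[0]
        dxhat = grad * self.gamma
        return (
            istd / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class ResidualBlock(Layer):
    """Two 3x3 convolutions with a skip connection and ReLU activations."""

    def __init__(self, channels, rng=None):
        self.conv1 = Conv2d(channels, channels, 3, 1, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, 1, 1, rng)
        self.relu_out = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        return self.relu_out.forward(h + x, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx + g


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def zero_grads(params):
    for p in params:
        p["grad"][...] = 0.0


class SGD:
    """SGD with momentum; learning rate supplied per step by a schedule."""

    def __init__(self, params, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p["value"]) for p in params]

    def step(self, lr):
        for p, v in zip(self.params, self.vel):
            g = p["grad"] + self.weight_decay * p["value"]
            v *= self.momentum
            v -= lr * g
            p["value"] += v


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"] + self.weight_decay * p["value"]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p["value"] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_warm_restarts(lr_max, t0, t_mult=2, lr_min=0.0):
    """Schedule function step -> lr: cosine annealing with warm restarts
    (restart period t0 steps, multiplied by t_mult after each restart)."""

    def lr_at(step):
        period, start = t0, 0
        while step >= start + period:
            start += period
            period *= t_mult
        frac = (step - start) / period
        return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * frac))

    return lr_at


def save_params(path, layers_params, extra=None):
    arrays = {f"p{i}": p["value"] for i, p in enumerate(layers_params)}
    if extra:
        arrays.update(extra)
    np.savez(path, **arrays)


def load_params(path, layers_params):
    data = np.load(path)
    for i, p in enumerate(layers_params):
        p["value"][...] = data[f"p{i}"]
    return data
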