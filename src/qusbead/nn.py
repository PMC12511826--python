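"""Minimal CNN building blocks on numpy with hand-written backpropagation.

Implements exactly the operations the segmentation network needs — 2-D
convolution, 2x2 transposed convolution, batch normalization, ReLU, 2x2 max
pooling, binary cross-entropy with logits and an Adam optimizer. All arrays
are float32 in channels-last (NHWC) layout, which keeps the convolution
inner loops on contiguous memory: a 3x3 convolution is nine shifted
(N*H*W, C) x (C, C_out) BLAS matmuls instead of an im2col gather, an order
of magnitude faster in numpy. Every layer caches its forward intermediates
and exposes ``backward(grad)``; parameters are ``(array, grad)`` pairs
updated in place by the optimizer, so training is fully deterministic under
a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2x2", "BatchNorm2d", "ReLU", "MaxPool2x2",
    "Sequential", "Adam", "bce_with_logits", "sigmoid",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        pass


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """k x k 'same' convolution (k odd) on NHWC tensors via shifted matmuls."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator = None):
        if rng is None:
            rng = np.random.default_rng(0)
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        self.W = _he_init(rng, c_in * k * k, (k * k, c_in, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if self.k == 1:
            if train:
                self._xp = x
            y = x.reshape(-1, c) @ self.W[0] + self.b
            return y.reshape(n, h, w, self.c_out)
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        if train:
            self._xp = xp
        y = np.zeros((n * h * w, self.c_out), dtype=np.float32)
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            slab = xp[:, i:i + h, j:j + w, :].reshape(-1, c)
            y += slab @ self.W[idx]
        y += self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, grad):
        n, h, w, _ = grad.shape
        g = grad.reshape(-1, self.c_out)
        self.db[...] = g.sum(axis=0)
        if self.k == 1:
            x = self._xp
            self.dW[0] = x.reshape(-1, self.c_in).T @ g
            self._xp = None
            return (g @ self.W[0].T).reshape(n, h, w, self.c_in)
        xp = self._xp
        dxp = np.zeros_like(xp)
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            slab = xp[:, i:i + h, j:j + w, :].reshape(-1, self.c_in)
            self.dW[idx] = slab.T @ g
            dxp[:, i:i + h, j:j + w, :] += (g @ self.W[idx].T).reshape(n, h, w, self.c_in)
        self._xp = None
        p = self.pad
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W, "b": self.b}

    def load_state(self, state):
        self.W[...] = state["W"]
        self.b[...] = state["b"]


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, c_in, (c_in, 4 * c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if train:
            self._x = x
        y = x.reshape(-1, c) @ self.W  # (n*h*w, 4*c_out)
        y = y.reshape(n, h, w, 2, 2, self.c_out)
        out = y.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.c_out)
        return out + self.b

    def backward(self, grad):
        n, h2, w2, _ = grad.shape
        h, w = h2 // 2, w2 // 2
        self.db[...] = grad.sum(axis=(0, 1, 2))
        g = grad.reshape(n, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        g = np.ascontiguousarray(g).reshape(-1, 4 * self.c_out)
        x = self._x
        self.dW[...] = x.reshape(-1, self.c_in).T @ g
        self._x = None
        return (g @ self.W.T).reshape(n, h, w, self.c_in)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W, "b": self.b}

    def load_state(self, state):
        self.W[...] = state["W"]
        self.b[...] = state["b"]


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) on NHWC tensors."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._xhat = None
        self._invstd = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * invstd
        if train:
            self._xhat = xhat
            self._invstd = invstd
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, invstd = self._xhat, self._invstd
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = grad.sum(axis=(0, 1, 2))
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        dx = (self.gamma * invstd) * (grad - self.dbeta / m - xhat * (self.dgamma / m))
        self._xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.gamma[...] = state["gamma"]
        self.beta[...] = state["beta"]
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    def __init__(self):
        self._argmax = None
        self._xshape = None

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pool requires even spatial dimensions")
        self._xshape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        if train:
            self._argmax = idx
        return np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._xshape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], grad[:, :, :, None, :],
                          axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._argmax = None
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state(self, state):
        grouped: dict[int, dict[str, np.ndarray]] = {}
        for key, v in state.items():
            i, k = key.split(".", 1)
            grouped.setdefault(int(i), {})[k] = v
        for i, sub in grouped.items():
            self.layers[i].load_state(sub)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits and its gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return float(loss), grad
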