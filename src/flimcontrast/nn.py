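"""Minimal fully-connected neural-network primitives on NumPy.

Implements exactly the pieces the pixel classifier needs — dense layers,
batch normalization, ReLU, dropout, the Adam optimizer and global-norm
gradient clipping — with explicit forward/backward passes so that custom
losses (the contrastive clustering/separation terms and the consistency
regularizer) can inject gradients at arbitrary points of the network.

All layers follow the same contract: ``forward(x, training)`` caches what
``backward(grad)`` needs; parameters and their accumulated gradients are
exposed through ``params()`` / ``grads()`` as flat lists of arrays.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: a differentiable module with (possibly empty) parameters."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Linear(Layer):
    """Affine map ``x @ W + b`` with He-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, grad):
        assert self._x is not None, "backward() before forward(training=True)"
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm(Layer):
    """1-D batch normalization with learnable scale/shift.

    Training mode normalizes by batch statistics and updates running
    estimates; evaluation mode uses the running estimates, making the
    forward pass deterministic.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x, training=False, update_stats=True):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            if update_stats:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
            self._cache = None
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        assert self._cache is not None
        xhat, inv_std = self._cache
        n = xhat.shape[0]
        self.dgamma[...] = (grad * xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        gx = grad * self.gamma
        return (inv_std / n) * (
            n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0)
        )

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their joint L2 norm is at most ``max_norm``.

    Returns the pre-clipping global norm.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


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
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
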