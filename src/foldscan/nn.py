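"""Minimal dense-network building blocks with manual backpropagation.

The networks in this package are tiny (hundreds of parameters), so the
layers here implement exactly what is needed — Linear, BatchNorm1d, ReLU,
an MLP container and Adam — with explicit forward/backward passes on numpy
arrays.  Gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """Affine map ``y = x W^T + b`` with He-style initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(scale=scale, size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        self.dgamma += (dy * self._xhat).sum(axis=0)
        self.dbeta += dy.sum(axis=0)
        dxhat = dy * self.gamma
        if not self._train:
            return dxhat / self._std
        B = dy.shape[0]
        # standard batchnorm backward through batch mean and variance
        return (dxhat - dxhat.mean(axis=0)
                - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std


class MLP(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0

    def linear_param_count(self) -> int:
        """Trainable parameters in the fully connected layers only
        (batch-normalization scale/shift excluded)."""
        return sum(layer.n_params for layer in self.layers if isinstance(layer, Linear))


def mlp(dims: list[int], rng: np.random.Generator, batchnorm: bool = True) -> MLP:
    """Fully connected net with BatchNorm+ReLU after each hidden layer."""
    layers: list[Layer] = []
    for a, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
        layers.append(Linear(d_in, d_out, rng))
        if a < len(dims) - 2:
            if batchnorm:
                layers.append(BatchNorm(d_out))
            layers.append(ReLU())
    return MLP(layers)


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.grad_refs = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
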