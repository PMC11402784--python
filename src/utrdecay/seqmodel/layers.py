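"""Neural-network layers built on the autodiff engine.

Shapes follow the (batch, time, channels) convention of 1-D sequence
models. Initialization is Glorot-uniform from a layer-owned RNG so a
fixed seed reproduces the parameter draw exactly.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, maxpool1d


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Conv1D(Layer):
    """'Same'-padded 1-D convolution implemented as a sum of shifted
    matmuls (kernel sizes here are small)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = Tensor(_glorot(rng, fan_in, fan_out, (kernel, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        left = (self.kernel - 1) // 2
        right = self.kernel - 1 - left
        xp = x.pad_time(left, right)
        out = None
        for j in range(self.kernel):
            term = xp.slice_time(j, j + T).reshape(B * T, -1) @ _kernel_slice(self.W, j)
            out = term if out is None else out + term
        return (out + self.b).reshape(B, T, -1)

    def parameters(self):
        return [self.W, self.b]


def _kernel_slice(W: Tensor, j: int) -> Tensor:
    out = Tensor(W.data[j], parents=(W,))

    def bw(g):
        if W.requires_grad:
            W.grad[j] += g
    out._backward = bw
    return out


class LayerNorm(Layer):
    """Normalization over the channel axis, per position."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(n_features), requires_grad=True)
        self.b = Tensor(np.zeros(n_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (B, F) activations,
    with running statistics for inference."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.g = Tensor(np.ones(n_features), requires_grad=True)
        self.b = Tensor(np.zeros(n_features), requires_grad=True)
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu.data.ravel())
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var.data.ravel())
        else:
            mu = Tensor(self.run_mean[None, :])
            var = Tensor(self.run_var[None, :])
        return (x - mu) / ((var + self.eps) ** 0.5) * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training or self.rate <= 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.rate) / (1 - self.rate)
        return x * Tensor(mask)


class GRU(Layer):
    """Gated recurrent unit returning the final hidden state.

    With ``reverse=True`` the sequence is consumed from last position to
    first, so when inputs are right-padded the real 5' nucleotides are the
    last thing the network sees.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 reverse: bool = True):
        self.n_hidden = n_hidden
        self.reverse = reverse
        self.Wx = Tensor(_glorot(rng, n_in, 3 * n_hidden, (n_in, 3 * n_hidden)),
                         requires_grad=True)
        self.Wh = Tensor(_glorot(rng, n_hidden, 3 * n_hidden,
                                 (n_hidden, 3 * n_hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(3 * n_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        for t in order:
            xt = x.take_time(t)
            gx = xt @ self.Wx + self.b
            gh = h @ self.Wh
            z = (_cols(gx, 0, H) + _cols(gh, 0, H)).sigmoid()
            r = (_cols(gx, H, 2 * H) + _cols(gh, H, 2 * H)).sigmoid()
            n = (_cols(gx, 2 * H, 3 * H) + r * _cols(gh, 2 * H, 3 * H)).tanh()
            h = (1.0 - z) * n + z * h
        return h

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


def _cols(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[:, start:stop], parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.grad[:, start:stop] += g
    out._backward = bw
    return out


__all__ = ["Dense", "Conv1D", "LayerNorm", "BatchNorm", "Dropout", "GRU",
           "maxpool1d", "Layer"]
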