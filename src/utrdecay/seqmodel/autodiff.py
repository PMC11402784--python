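"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small 1-D convolutional + recurrent sequence
classifier: broadcast-aware elementwise ops, matmul, reductions, slicing,
max-pooling and a fused softmax cross-entropy. Gradients flow through a
dynamically built graph released after each backward pass; the same
mechanism supplies input gradients for attribution.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad down to the given (broadcast-source) shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------- graph engine

    def backward(self, grad: np.ndarray | None = None) -> None:
        # iterative topological sort: recurrent graphs get deep
        topo, seen = [], set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if not node.requires_grad:
                continue
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # --------------------------------------------------------- arithmetic

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data ** 2,
                                           other.data.shape)
        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1)
        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g
        out._backward = bw
        return out

    __matmul__ = matmul

    # --------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.full_like(self.data, g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------- elementwise

    def _unary(self, value: np.ndarray, local_grad: np.ndarray) -> "Tensor":
        out = Tensor(value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * local_grad
        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        return self._unary(np.maximum(self.data, 0.0), (self.data > 0).astype(float))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._unary(s, s * (1.0 - s))

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        return self._unary(t, 1.0 - t ** 2)

    def exp(self) -> "Tensor":
        e = np.exp(np.clip(self.data, -60, 60))
        return self._unary(e, e)

    def abs(self) -> "Tensor":
        return self._unary(np.abs(self.data), np.sign(self.data))

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        return self._unary(r, 0.5 / np.maximum(r, 1e-12))

    # ------------------------------------------------------ shape / slices

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)
        out._backward = bw
        return out

    def slice_time(self, start: int, stop: int) -> "Tensor":
        """x[:, start:stop, ...] on a (B, T, ...) tensor."""
        out = Tensor(self.data[:, start:stop], parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad[:, start:stop] += g
        out._backward = bw
        return out

    def take_time(self, t: int) -> "Tensor":
        """x[:, t, :] on a (B, T, C) tensor -> (B, C)."""
        out = Tensor(self.data[:, t, :], parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.grad[:, t, :] += g
        out._backward = bw
        return out

    def pad_time(self, left: int, right: int) -> "Tensor":
        """Zero-pad the time axis of a (B, T, C) tensor."""
        out = Tensor(np.pad(self.data, ((0, 0), (left, right), (0, 0))),
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                T = self.data.shape[1]
                self.grad += g[:, left : left + T]
        out._backward = bw
        return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling on the time axis of (B, T, C);
    a trailing remainder shorter than ``pool`` is dropped."""
    B, T, C = x.data.shape
    T_out = T // pool
    view = x.data[:, : T_out * pool].reshape(B, T_out, pool, C)
    idx = view.argmax(axis=2)
    out = Tensor(view.max(axis=2), parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros((B, T_out, pool, C))
        b, t, c = np.ogrid[:B, :T_out, :C]
        gx[b, t, idx, c] = g
        x.grad[:, : T_out * pool] += gx.reshape(B, T_out * pool, C)
    out._backward = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over (B, K) logits and one-hot targets."""
    p = softmax(logits.data)
    B = logits.data.shape[0]
    loss = float(-(targets * np.log(np.maximum(p, 1e-12))).sum() / B)
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            logits.grad += g * (p - targets) / B
    out._backward = bw
    return out


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clipnorm: float | None = None):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clipnorm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clipnorm:
                grads = [g * (self.clipnorm / total) for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
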