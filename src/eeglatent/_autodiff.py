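"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine covering exactly the operations
the autoencoders need: broadcast arithmetic, (batched) matrix products,
ReLU, exp, softmax, reductions, reshapes and basic slicing, plus an Adam
optimizer.  Everything is float64 and fully deterministic, which keeps
model training bit-reproducible for a fixed seed.  Gradient correctness
is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        # parents: tuple of (Tensor, vjp) where vjp maps the output gradient
        # to this parent's gradient contribution.
        self._parents = parents

    # -- graph -------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, vjp in node._parents:
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            (
                (self, lambda g, s=self.data.shape: _unbroadcast(g, s)),
                (other, lambda g, s=other.data.shape: _unbroadcast(g, s)),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, ((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            (
                (self, lambda g, o=other.data, s=self.data.shape: _unbroadcast(g * o, s)),
                (other, lambda g, m=self.data, s=other.data.shape: _unbroadcast(g * m, s)),
            ),
        )
        return out

    __rmul__ = __mul__

    def __pow__(self, p: float):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(
            self.data**p,
            ((self, lambda g, d=self.data: g * p * d ** (p - 1)),),
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            (
                (
                    self,
                    lambda g, o=other.data, s=self.data.shape: _unbroadcast(
                        g @ o.swapaxes(-1, -2), s
                    ),
                ),
                (
                    other,
                    lambda g, m=self.data, s=other.data.shape: _unbroadcast(
                        m.swapaxes(-1, -2) @ g, s
                    ),
                ),
            ),
        )
        return out

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor(np.where(mask, self.data, 0.0), ((self, lambda g: g * mask),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor(y, ((self, lambda g: g * y),))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)

        def vjp(g, y=y, axis=axis):
            return y * (g - (g * y).sum(axis=axis, keepdims=True))

        return Tensor(y, ((self, vjp),))

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape), ((self, lambda g: g.reshape(old)),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            self.data.swapaxes(a, b), ((self, lambda g: g.swapaxes(a, b)),)
        )

    def __getitem__(self, idx):
        def vjp(g, idx=idx, shape=self.data.shape):
            out = np.zeros(shape)
            out[idx] = g
            return out

        return Tensor(self.data[idx], ((self, vjp),))

    # -- reductions ------------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def vjp(g, axis=axis, keepdims=keepdims, shape=self.data.shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), ((self, vjp),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- misc ------------------------------------------------------------------

    def item(self) -> float:
        return float(self.data)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Fan-based uniform initialization."""
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)
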