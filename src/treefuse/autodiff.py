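"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based scalar-loss engine supporting exactly the operations the
model needs: broadcast add/mul/div, matmul, ReLU, square root, axis
means/sums, concatenation and a fused softmax cross-entropy. Gradients
follow standard broadcasting rules (summed back to the parameter shape).

Kept deliberately tiny: no graphs across batches, no higher-order
derivatives, float64 throughout for reproducibility on CPU.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "softmax_cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- ops ---------------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(out.grad, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(
                    -out.grad * self.data / other.data ** 2, other.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad or other._parents:
                other._accum(self.data.T @ out.grad)
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        out._parents = (self,)

        def bw():
            self._accum(out.grad * (self.data > 0))
        out._backward = bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), self.requires_grad)
        out._parents = (self,)

        def bw():
            self._accum(out.grad * 0.5 / out.data)
        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad)
        out._parents = (self,)

        def bw():
            self._accum(np.full_like(self.data, out.grad))
        out._backward = bw
        return out

    def mean(self, axis: int = 0, keepdims: bool = True):
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        out._parents = (self,)
        n = self.data.shape[axis]

        def bw():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g / n, self.data.shape).copy())
        out._backward = bw
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw():
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad or t._parents:
                t._accum(out.grad[tuple(sl)])
            start += s
    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray,
                          clip: float = 1e-12) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy with a fused softmax backward.

    Returns the scalar loss tensor and the softmax probabilities
    (plain array, for metrics). Probabilities are clipped away from
    zero inside the log for numerical safety.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = probs.shape[0]
    loss_val = -np.sum(onehot * np.log(np.clip(probs, clip, 1.0))) / n
    out = Tensor(loss_val, logits.requires_grad)
    out._parents = (logits,)

    def bw():
        logits._accum(out.grad * (probs - onehot) / n)
    out._backward = bw
    return out, probs


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
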