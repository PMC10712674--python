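"""Lightweight reverse-mode automatic differentiation on numpy arrays.

The spiking model in this package needs gradients through a handful of
operations only: matrix products, broadcast arithmetic, softmax, leaky ReLU,
reductions, and two custom recurrences (the Axon IIR filter and the Soma
spike loop, which register their own backward rules in
:mod:`fractalsnn.neuron`).  This module provides exactly that: a ``Tensor``
wrapping a float64 ndarray, a topologically-sorted backward pass, and an Adam
optimizer.  Everything is double precision and deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    ``data`` is always a float64 ndarray.  ``grad`` is populated by
    :meth:`backward`.  Graph edges are stored as ``(parent, local_backward)``
    pairs where ``local_backward`` maps the incoming gradient to the parent's
    gradient contribution.
    """

    __slots__ = ("data", "grad", "requires_grad", "_edges")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._edges: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def from_op(data: np.ndarray,
                edges: Sequence[tuple["Tensor", Callable]]) -> "Tensor":
        """Create a result tensor wired to its parents."""
        out = Tensor(data)
        live = [(p, fn) for p, fn in edges if p.requires_grad or p._edges]
        if live:
            out.requires_grad = True
            out._edges = live
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        # topological order by depth-first traversal
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
            for parent, _ in node._edges:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._edges:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._as_tensor(other)
        a, b = self, other
        return Tensor.from_op(a.data + b.data, [
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor.from_op(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other) -> "Tensor":
        return self + (-self._as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return self._as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._as_tensor(other)
        a, b = self, other
        return Tensor.from_op(a.data * b.data, [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / float(other))

    def __matmul__(self, other) -> "Tensor":
        other = self._as_tensor(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor.from_op(a.data @ b.data, [
            (a, lambda g: g @ b.data.T),
            (b, lambda g: a.data.T @ g),
        ])

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor.from_op(self.data.reshape(shape),
                              [(self, lambda g: g.reshape(old))])

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))
        return Tensor.from_op(self.data.transpose(axes),
                              [(self, lambda g: g.transpose(inv))])

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, key) -> "Tensor":
        shape = self.data.shape

        def back(g: np.ndarray) -> np.ndarray:
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, key, g)
            return full

        return Tensor.from_op(self.data[key], [(self, back)])

    # -- reductions & nonlinearities ------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape

        def back(g: np.ndarray) -> np.ndarray:
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, shape).copy()

        return Tensor.from_op(self.data.sum(axis=axis, keepdims=keepdims),
                              [(self, back)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, negative_slope)
        return Tensor.from_op(self.data * mask, [(self, lambda g: g * mask)])

    def softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        s = np.exp(x - x.max(axis=axis, keepdims=True))
        s /= s.sum(axis=axis, keepdims=True)

        def back(g: np.ndarray) -> np.ndarray:
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor.from_op(s, [(self, back)])


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def make_back(i: int) -> Callable[[np.ndarray], np.ndarray]:
        sl = [slice(None)] * tensors[i].ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor.from_op(
        np.concatenate([t.data for t in tensors], axis=axis),
        [(t, make_back(i)) for i, t in enumerate(tensors)])


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under rows of ``logits`` (B, z).

    Forward uses a numerically stable log-softmax; backward is the usual
    ``(softmax - onehot) / B``.
    """
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    softmax = np.exp(logp)
    onehot = np.zeros_like(z)
    onehot[np.arange(n), labels] = 1.0

    def back(g: np.ndarray) -> np.ndarray:
        return g * (softmax - onehot) / n

    return Tensor.from_op(np.asarray(loss), [(logits, back)])


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
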