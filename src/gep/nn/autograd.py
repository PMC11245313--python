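"""A small reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the binding-site models need: dense
linear algebra, elementwise nonlinearities, broadcasting arithmetic,
row gather / segment-sum for message passing on graphs, and max/mean
reductions for point-cloud pooling.  Gradients are accumulated by a
topological-order sweep over the recorded operation graph.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "gather", "scatter_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # ----------------------------------------------------- elementwise
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope)
        return self._make(self.data * mult, (self,), lambda g: (g * mult,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(s, (self,), lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1 - t**2),))

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        return self._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(out, (self,), lambda g: (g * sig,))

    def clamp(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return self._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    # ------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int):
        """Max along one axis; gradient flows to the (first) argmax."""
        arg = np.argmax(self.data, axis=axis)
        out = np.max(self.data, axis=axis)

        def backward(g):
            grad = np.zeros_like(self.data)
            idx = list(np.indices(out.shape))
            idx.insert(axis % self.data.ndim, arg)
            grad[tuple(idx)] = g
            return (grad,)

        return self._make(out, (self,), backward)

    # ------------------------------------------------------- reshaping
    def reshape(self, *shape):
        orig = self.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    # -------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        # leaves that appeared only as direct targets
        for t in topo:
            if t._backward is None and t.grad is None and id(t) in grads:
                t.grad = grads[id(t)]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]``; scatter-add on the way back."""
    index = np.asarray(index, dtype=int)

    def backward(g):
        grad = np.zeros_like(t.data)
        np.add.at(grad, index, g)
        return (grad,)

    return Tensor._make(t.data[index], (t,), backward)


def scatter_sum(src: Tensor, index: np.ndarray, n: int) -> Tensor:
    """out[i] = sum of src rows whose index equals i (message aggregation)."""
    index = np.asarray(index, dtype=int)
    out = np.zeros((n,) + src.data.shape[1:], dtype=float)
    np.add.at(out, index, src.data)
    return Tensor._make(out, (src,), lambda g: (g[index],))
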