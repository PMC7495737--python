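"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The trainable network in this package (embeddings, multi-head attention,
parallel convolutions, capsule routing, dense softmax head) is expressed as a
graph of :class:`Tensor` operations; gradients for the Adam optimizer come
from a single tape walk.  Only the primitives the model needs are provided —
this is not a general framework.

All arithmetic is float64; broadcasting follows NumPy rules, with gradients
sum-reduced back to each operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "pad_axis"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a, b):
        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return self._make(self.data[key], (self,), bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        hit = self.data == out_data
        # split ties evenly so the gradient stays well defined
        hit = hit / hit.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(gg * hit)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(data, (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        pos = self.data > 0

        def bw(g):
            self._accumulate(g * pos)

        return self._make(self.data * pos, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        """Numerically stable softmax along `axis`."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                t._accumulate(piece)

        out._backward = bw
    return out


def pad_axis(t: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad `t` along `axis`."""
    pads = [(0, 0)] * t.ndim
    pads[axis] = (before, after)
    n = t.shape[axis]
    sl = [slice(None)] * t.ndim
    sl[axis] = slice(before, before + n)
    sl = tuple(sl)

    def bw(g):
        t._accumulate(g[sl])

    return t._make(np.pad(t.data, pads), (t,), bw)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather `weight[ids]` with scatter-add backward."""
    ids = np.asarray(ids)

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.shape[-1]))
        weight._accumulate(full)

    return weight._make(weight.data[ids], (weight,), bw)
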