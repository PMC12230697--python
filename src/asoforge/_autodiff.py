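"""Minimal reverse-mode tensor autodiff on NumPy arrays.

Supports exactly the operations the graph-transformer ranker needs:
broadcasting arithmetic, general ``einsum``, softmax, sigmoid, ReLU,
reductions, reshaping and layer normalization. Gradients are accumulated
by topological-order backpropagation from a scalar loss. An ``inference``
context disables graph construction so scoring retains no intermediates.

Not a general framework: no views/in-place semantics, no higher-order
derivatives, no ellipsis in einsum subscripts.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def inference_mode():
    """Disable gradient-graph construction within the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
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

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], Iterable[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this scalar to all reachable leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g), parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g
            if node is not self:
                node.grad = None  # free intermediate gradients eagerly
                node._parents = ()
                node._backward = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar fast path, keeps dtype
            other = float(other)  # NumPy scalars are strong under NEP 50
            return Tensor._make(self.data + other, (self,), lambda g: (g,))
        other = _as_tensor(other)
        return Tensor._make(
            self.data + other.data, (self, other), lambda g: (g, g)
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            other = float(other)
            return Tensor._make(self.data - other, (self,), lambda g: (g,))
        other = _as_tensor(other)
        return Tensor._make(
            self.data - other.data, (self, other), lambda g: (g, -g)
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            o = float(other)
            return Tensor._make(self.data * o, (self,), lambda g: (g * o,))
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / (other.data**2)),
        )

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

        return Tensor._make(s, (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def einsum(subscripts: str, *tensors: Tensor) -> Tensor:
    """Differentiable ``np.einsum`` with explicit subscripts (no ellipsis)."""
    ins, out_sub = subscripts.replace(" ", "").split("->")
    in_subs = ins.split(",")
    if len(in_subs) != len(tensors):
        raise ValueError("subscript/operand count mismatch")
    datas = [t.data for t in tensors]
    result = np.einsum(subscripts, *datas, optimize=True)

    def backward(g):
        grads = []
        for k, sub_k in enumerate(in_subs):
            others = [s for i, s in enumerate(in_subs) if i != k]
            other_data = [d for i, d in enumerate(datas) if i != k]
            spec = ",".join([out_sub] + others) + "->" + sub_k
            grads.append(np.einsum(spec, g, *other_data, optimize=True))
        return grads

    return Tensor._make(result, tuple(tensors), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gain + bias


def relu(x: Tensor) -> Tensor:
    return x.relu()
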