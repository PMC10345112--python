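"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations needed by the sequence models in
this package: broadcast arithmetic, (batched) matrix products, the usual
activations, stable softmax / log-softmax, reductions, indexing, reshaping
and concatenation.  Gradients are accumulated in float64 throughout; graphs
are walked once in reverse topological order.

Design constraints:
  * deterministic — no op may introduce platform-dependent randomness;
  * gradients of every primitive are unit-tested against central finite
    differences (see the test suite), so new primitives must ship a check.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data: ArrayLike, requires_grad: bool = False,
                 name: Optional[str] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()
        self.name = name

    # ---- plumbing -------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(fwd(self.data, other.data))
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = (self, other)

            def _backward(g: np.ndarray) -> None:
                if self.requires_grad:
                    self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data),
                                                  self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data),
                                                   other.data.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                self._accumulate(g * p * self.data ** (p - 1))

            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data)
        if self.requires_grad or other.requires_grad:
            out.requires_grad = True
            out._parents = (self, other)

            def _backward(g: np.ndarray) -> None:
                a, b = self.data, other.data
                if self.requires_grad:
                    if b.ndim == 1:
                        ga = np.multiply.outer(g, b) if g.ndim else g * b
                    else:
                        ga = g @ np.swapaxes(b, -1, -2)
                    self._accumulate(_unbroadcast(np.asarray(ga), a.shape))
                if other.requires_grad:
                    if a.ndim == 1:
                        gb = np.multiply.outer(a, g) if g.ndim else a * g
                    else:
                        gb = np.swapaxes(a, -1, -2) @ g
                    other._accumulate(_unbroadcast(np.asarray(gb), b.shape))

            out._backward = _backward
        return out

    # ---- unary ops ------------------------------------------------------

    def _unary(self, fwd, bwd) -> "Tensor":
        out = Tensor(fwd(self.data))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                self._accumulate(bwd(g, self.data, out.data))

            out._backward = _backward
        return out

    def tanh(self):
        return self._unary(np.tanh, lambda g, x, y: g * (1.0 - y * y))

    def sigmoid(self):
        def fwd(x):
            out = np.empty_like(x)
            pos = x >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            ex = np.exp(x[~pos])
            out[~pos] = ex / (1.0 + ex)
            return out
        return self._unary(fwd, lambda g, x, y: g * y * (1.0 - y))

    def relu(self):
        return self._unary(lambda x: np.maximum(x, 0.0),
                           lambda g, x, y: g * (x > 0))

    def exp(self):
        return self._unary(np.exp, lambda g, x, y: g * y)

    def log(self):
        return self._unary(np.log, lambda g, x, y: g / x)

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, x, y: g * 0.5 / y)

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                self._accumulate(g.reshape(self.data.shape))

            out._backward = _backward
        return out

    def transpose(self, axes: Sequence[int]):
        out = Tensor(self.data.transpose(axes))
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            inv = np.argsort(axes)

            def _backward(g: np.ndarray) -> None:
                self._accumulate(g.transpose(inv))

            out._backward = _backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

            out._backward = _backward
        return out

    # ---- softmax family -------------------------------------------------

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g: np.ndarray) -> None:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))

            out._backward = _backward
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls)
        if self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            sm = np.exp(ls)

            def _backward(g: np.ndarray) -> None:
                self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

            out._backward = _backward
        return out

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along `axis`."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _backward(g: np.ndarray) -> None:
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = _backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Differentiable stack of equally-shaped tensors along a new axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def _backward(g: np.ndarray) -> None:
            parts = np.moveaxis(g, axis, 0)
            for t, piece in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _backward
    return out


def parameters_of(tree: Iterable) -> list[Tensor]:
    """Flatten a nested iterable of Tensors/containers into a parameter list."""
    out: list[Tensor] = []
    for item in tree:
        if isinstance(item, Tensor):
            out.append(item)
        else:
            out.extend(parameters_of(item))
    return out
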