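"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides the :class:`Tensor` graph node plus a small set of differentiable
primitives (elementwise math, reductions, matmul, shape ops, ``gammaln``)
sufficient to express the Transformer backbone, the LSTM baseline and the
Student-t mixture likelihood in closed form.  Everything is float64.

Module-level functions (``exp``, ``log1p``, ``gammaln`` ...) dispatch on
their argument type: a :class:`Tensor` builds graph nodes, a plain array or
scalar falls through to numpy/scipy.  This lets the density mathematics in
:mod:`flockcast.studentt` be written once and evaluated both ways.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "exp",
    "log",
    "log1p",
    "sqrt",
    "tanh",
    "erf",
    "sigmoid",
    "softplus",
    "gammaln",
    "logsumexp",
    "softmax",
    "concatenate",
    "stack",
    "where_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn: Callable | None = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward_fn: Callable) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward_fn = backward_fn
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (LSTM unrolls)
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g, dtype=np.float64), parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._node(self.data + other.data, (self, other), lambda g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._node(
            self.data * other.data,
            (self, other),
            lambda g, a=self, b=other: (g * b.data, g * a.data),
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._node(self.data - other.data, (self, other), lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._node(
            self.data / other.data,
            (self, other),
            lambda g, a=self, b=other: (g / b.data, -g * a.data / (b.data ** 2)),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor._node(
            self.data ** p,
            (self,),
            lambda g, a=self: (g * p * a.data ** (p - 1),),
        )

    # -- elementwise ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g, o=out_data: (g * o,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g, a=self: (g / a.data,))

    def log1p(self):
        return Tensor._node(np.log1p(self.data), (self,), lambda g, a=self: (g / (1.0 + a.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._node(out_data, (self,), lambda g, o=out_data: (g * 0.5 / o,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._node(out_data, (self,), lambda g, o=out_data: (g * (1.0 - o * o),))

    def erf(self):
        return Tensor._node(
            _sp.erf(self.data),
            (self,),
            lambda g, a=self: (g * (2.0 / math.sqrt(math.pi)) * np.exp(-a.data ** 2),),
        )

    def sigmoid(self):
        out_data = _sp.expit(self.data)
        return Tensor._node(out_data, (self,), lambda g, o=out_data: (g * o * (1.0 - o),))

    def softplus(self):
        # stable log(1 + e^x); derivative is the logistic sigmoid
        out_data = np.logaddexp(0.0, self.data)
        return Tensor._node(out_data, (self,), lambda g, a=self: (g * _sp.expit(a.data),))

    def gammaln(self):
        return Tensor._node(
            _sp.gammaln(self.data),
            (self,),
            lambda g, a=self: (g * _sp.psi(a.data),),
        )

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._node(
            np.clip(self.data, lo, hi),
            (self,),
            lambda g, m=mask: (g * m,),
        )

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape),)

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g, s=old: (g.reshape(s),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,), lambda g, inv=inv: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._node(out_data, (self,), bwd)

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (ga, gb)

        return Tensor._node(out_data, (self, other), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Dispatching functional API: Tensor -> graph op, ndarray/scalar -> numpy.
# ---------------------------------------------------------------------------

def _dispatch(name: str, np_fn: Callable):
    def fn(x):
        if isinstance(x, Tensor):
            return getattr(x, name)()
        return np_fn(x)

    fn.__name__ = name
    return fn


exp = _dispatch("exp", np.exp)
log = _dispatch("log", np.log)
log1p = _dispatch("log1p", np.log1p)
sqrt = _dispatch("sqrt", np.sqrt)
tanh = _dispatch("tanh", np.tanh)
erf = _dispatch("erf", _sp.erf)
sigmoid = _dispatch("sigmoid", _sp.expit)
softplus = _dispatch("softplus", lambda x: np.logaddexp(0.0, x))
gammaln = _dispatch("gammaln", _sp.gammaln)


def logsumexp(x, axis: int = -1):
    """Stable log-sum-exp; differentiable when given a Tensor."""
    if isinstance(x, Tensor):
        m = np.max(x.data, axis=axis, keepdims=True)  # constant shift
        shifted = x - Tensor(m)
        return (shifted.exp().sum(axis=axis)).log() + Tensor(np.squeeze(m, axis=axis))
    return _sp.logsumexp(x, axis=axis)


def softmax(x, axis: int = -1):
    if isinstance(x, Tensor):
        m = np.max(x.data, axis=axis, keepdims=True)
        e = (x - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._node(out_data, tensors, bwd)


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select between two tensors with a constant boolean mask."""
    a, b = as_tensor(a), as_tensor(b)
    m = np.asarray(mask, dtype=bool)
    return Tensor._node(
        np.where(m, a.data, b.data),
        (a, b),
        lambda g: (g * m, g * ~m),
    )
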