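"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: enough vectorized primitives (broadcasting
arithmetic, batched matmul, reductions, reshapes, gathers, the usual
nonlinearities) to express Transformer blocks and spectral filtering, with
gradients checked against finite differences in the test suite.  All state
is explicit; there is no global tape.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "Parameter", "concat", "stack", "erf", "gelu", "sigmoid",
           "softmax", "layer_norm", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum along broadcast (size-1) axes
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @staticmethod
    def active() -> bool:
        return _NoGrad._depth > 0


def no_grad() -> _NoGrad:
    """Context manager disabling graph construction (e.g. momentum targets)."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        if requires_grad and _NoGrad.active() and _backward is not None:
            requires_grad = False
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents) if requires_grad else ()
        self._backward = _backward if requires_grad else None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = np.zeros_like(node.data)
            node.grad = node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    def _binary(self, other, fwd, bwd) -> "Tensor":
        other = Tensor._lift(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            return bwd(g, self, other)

        return Tensor(out_data, req, (self, other), backward if req else None)

    def __add__(self, other):
        return self._binary(
            other, lambda a, b: a + b,
            lambda g, x, y: ((x, _unbroadcast(g, x.shape)),
                             (y, _unbroadcast(g, y.shape))))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(
            other, lambda a, b: a - b,
            lambda g, x, y: ((x, _unbroadcast(g, x.shape)),
                             (y, _unbroadcast(-g, y.shape))))

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(
            other, lambda a, b: a * b,
            lambda g, x, y: ((x, _unbroadcast(g * y.data, x.shape)),
                             (y, _unbroadcast(g * x.data, y.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other, lambda a, b: a / b,
            lambda g, x, y: ((x, _unbroadcast(g / y.data, x.shape)),
                             (y, _unbroadcast(-g * x.data / y.data ** 2, y.shape))))

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        req = self.requires_grad
        return Tensor(-self.data, req, (self,),
                      (lambda g: ((self, -g),)) if req else None)

    def __pow__(self, exponent: float):
        if not isinstance(exponent, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** exponent
        req = self.requires_grad

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor(out, req, (self,), backward if req else None)

    # -- matmul --------------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = self.data @ other.data
        req = self.requires_grad or other.requires_grad

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:            # dot product
                ga, gb = g * b, g * a
            elif b.ndim == 1:                          # (..., n, k) @ (k,)
                ga = _unbroadcast(g[..., None] * b, a.shape)
                gb = _unbroadcast(
                    (np.swapaxes(a, -1, -2) @ g[..., None])[..., 0], b.shape)
            elif a.ndim == 1:                          # (k,) @ (..., k, m)
                ga = _unbroadcast((b @ g[..., None])[..., 0], a.shape)
                gb = _unbroadcast(a[:, None] * g[..., None, :], b.shape)
            else:                                      # batched matrix product
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ((self, ga), (other, gb))

        return Tensor(out, req, (self, other), backward if req else None)

    def __rmatmul__(self, other):
        return Tensor._lift(other).__matmul__(self)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out, req, (self,), backward if req else None)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            math.prod(self.data.shape[a] for a in
                      (axis if isinstance(axis, tuple) else (axis,))))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        req = self.requires_grad

        def backward(g):
            return ((self, g.reshape(self.data.shape)),)

        return Tensor(out, req, (self,), backward if req else None)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        out = self.data.transpose(axes)
        inv = np.argsort(axes)
        req = self.requires_grad

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor(out, req, (self,), backward if req else None)

    def __getitem__(self, idx) -> "Tensor":
        out = self.data[idx]
        req = self.requires_grad

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(out, req, (self,), backward if req else None)

    # -- nonlinearities ------------------------------------------------------
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        req = self.requires_grad
        return Tensor(out, req, (self,),
                      (lambda g: ((self, g * out),)) if req else None)

    def log(self) -> "Tensor":
        out = np.log(self.data)
        req = self.requires_grad
        return Tensor(out, req, (self,),
                      (lambda g: ((self, g / self.data),)) if req else None)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        req = self.requires_grad
        return Tensor(out, req, (self,),
                      (lambda g: ((self, g * (1.0 - out ** 2)),)) if req else None)


class Parameter(Tensor):
    """A leaf tensor that always participates in gradient computation."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions ----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        pieces = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, pieces))

    return Tensor(out, req, tensors, backward if req else None)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.reshape(t.data.shape))
                     for t, p in zip(tensors, pieces))

    return Tensor(out, req, tensors, backward if req else None)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out = _special.expit(x.data)
    req = x.requires_grad
    return Tensor(out, req, (x,),
                  (lambda g: ((x, g * out * (1.0 - out)),)) if req else None)


def erf(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out = _special.erf(x.data)
    req = x.requires_grad
    two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
    return Tensor(out, req, (x,),
                  (lambda g: ((x, g * two_over_sqrt_pi * np.exp(-x.data ** 2)),))
                  if req else None)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = Tensor._lift(x)
    return x * (erf(x * (1.0 / math.sqrt(2.0))) + 1.0) * 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    shift = np.max(x.data, axis=axis, keepdims=True)  # detached max-shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor | None = None,
               beta: Tensor | None = None, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the trailing axis."""
    x = Tensor._lift(x)
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    out = centered / (var + eps) ** 0.5
    if gamma is not None:
        out = out * gamma
    if beta is not None:
        out = out + beta
    return out
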