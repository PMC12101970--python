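"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine (in the spirit of micrograd, but on whole arrays)
providing exactly the operations the mesh sequence model needs: broadcasted
arithmetic, dense and sparse matrix products, reductions, indexing/gather,
elementwise nonlinearities, softmax and layer normalisation. Gradients are
accumulated by a topological backward sweep; correctness is established by
finite-difference checks in the test suite.

The engine intentionally supports only float arrays and a static graph per
forward pass. Use :func:`no_grad` around inference-only code to skip tape
construction.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse as _sparse

_grad_enabled = True


@contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: Tuple["Tensor", ...] = _parents if self.requires_grad else ()
        self._backward: Optional[Callable[[np.ndarray], None]] = (
            _backward if self.requires_grad else None
        )

    # -- graph construction helpers ----------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add ``grad`` into this node's gradient buffer. ``fresh=True``
        promises the array was newly allocated by the caller (never a view of
        another node's buffer), letting us adopt it without a copy."""
        if self.grad is None:
            if fresh and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        rq = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                gg = _unbroadcast(g, self.data.shape)
                self._accumulate(gg, fresh=gg is not g)
            if other.requires_grad:
                gg = _unbroadcast(g, other.data.shape)
                other._accumulate(gg, fresh=gg is not g)

        return Tensor(out_data, rq, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g, fresh=True)

        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape), fresh=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape), fresh=True)

        return Tensor(self.data * other.data, rq, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad
        out = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape), fresh=True)
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape),
                    fresh=True,
                )

        return Tensor(out, rq, (self, other), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2), fresh=True)
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g, fresh=True)

        return Tensor(self.data @ other.data, rq, (self, other), bw)

    def __pow__(self, p: float):
        out = self.data**p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1), fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy(), fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = self.data.reshape(*shape)

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out, self.requires_grad, (self,), bw)

    def transpose(self, *axes):
        axes = axes or None
        out = self.data.transpose(axes)
        inv = np.argsort(axes) if axes else None

        def bw(g):
            self._accumulate(g.transpose(inv) if inv is not None else g.transpose())

        return Tensor(out, self.requires_grad, (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full, fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out, fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data, fresh=True)

        return Tensor(np.log(self.data), self.requires_grad, (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out, fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out**2), fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)

    def relu(self):
        out = np.maximum(self.data, 0.0)

        def bw(g):
            self._accumulate(g * (self.data > 0), fresh=True)

        return Tensor(out, self.requires_grad, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, dtype=np.float64) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


# -- composite / special ops -------------------------------------------------


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    rq = any(t.requires_grad for t in ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, rq, tuple(ts), bw)


def spmm(m: _sparse.spmatrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable) matrix product."""
    x = as_tensor(x)
    if not (x.requires_grad and _grad_enabled):
        return Tensor(m @ x.data)
    mt = m.T.tocsr()

    def bw(g):
        x._accumulate(mt @ g, fresh=True)

    return Tensor(m @ x.data, x.requires_grad, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot), fresh=True)

    return Tensor(out, x.requires_grad, (x,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learned scale/shift."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data
    rq = x.requires_grad or gamma.requires_grad or beta.requires_grad
    d = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate(
                _unbroadcast(g * xhat, gamma.data.shape)
            )
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            x._accumulate(
                inv / d * (d * gx - gx.sum(axis=-1, keepdims=True)
                           - xhat * (gx * xhat).sum(axis=-1, keepdims=True)),
                fresh=True,
            )

    return Tensor(out, rq, (x, gamma, beta), bw)


def norm_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Euclidean norm along the last axis: sqrt(sum(x^2) + eps)."""
    return ((x * x).sum(axis=-1) + eps).sqrt()


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask.astype(x.data.dtype))


# -- optimizer ----------------------------------------------------------------


class Adam:
    """Adam with fixed learning rate (no schedule, no weight decay)."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, grad_clip: Optional[float] = None) -> None:
        self.t += 1
        if grad_clip is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params.values() if p.grad is not None)
            )
            if total > grad_clip:
                scale = grad_clip / (total + 1e-12)
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad *= scale
        # bias correction folded into the step size (standard reformulation)
        alpha = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            g *= g
            g *= 1 - self.b2
            v += g
            denom = np.sqrt(v)
            denom += self.eps
            np.divide(m, denom, out=denom)
            denom *= alpha
            p.data -= denom
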