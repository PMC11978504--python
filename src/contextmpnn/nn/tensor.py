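"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the message-passing networks need: broadcasted
arithmetic, dense linear maps, reductions, gathers along the leading axis,
concatenation, stable (log-)softmax, and a handful of scalar nonlinearities
(including log I0 for circular-normal likelihoods). Gradients accumulate into
``Tensor.grad`` after ``backward()`` on a scalar loss.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy import special as _special

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    # -- graph plumbing ----------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*inputs: Tensor) -> bool:
    return grad_enabled() and any(t.requires_grad for t in inputs)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def linear(x, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """``y = x @ weight.T + bias`` with ``weight`` of shape (out, in)."""
    x = as_tensor(x)
    n_in = weight.data.shape[1]
    lead = x.data.shape[:-1]
    x2 = x.data.reshape(-1, n_in)
    y = x2 @ weight.data.T
    if bias is not None:
        y = y + bias.data
    y = y.reshape(*lead, weight.data.shape[0])

    def backward(g):
        g2 = g.reshape(-1, weight.data.shape[0])
        if x.requires_grad:
            x._accumulate((g2 @ weight.data).reshape(x.data.shape))
        if weight.requires_grad:
            weight._accumulate(g2.T @ x2)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- reductions / shaping --------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[ax] for ax in axis]))
    else:
        n = a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[key]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

    return _make(out_data, (a,), backward)


def concatenate(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = np.broadcast_to(a.data, shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))

    return _make(out_data, (a,), backward)


def expand_axis(a, axis: int, size: int) -> Tensor:
    """Insert a broadcast axis of the given size (out of place)."""
    a = as_tensor(a)
    ndim = a.data.ndim + 1
    axis = axis % ndim
    shape = list(a.data.shape)
    shape.insert(axis, 1)
    out_shape = list(shape)
    out_shape[axis] = size
    return broadcast_to(reshape(a, tuple(shape)), tuple(out_shape))


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Index the leading axis with an integer array: out[i, k, ...] = a[index[i, k], ...]."""
    a = as_tensor(a)
    index = np.asarray(index)
    out_data = a.data[index]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, index.ravel(), g.reshape(-1, *a.data.shape[1:]))
            a._accumulate(full)

    return _make(out_data, (a,), backward)


# -- nonlinearities --------------------------------------------------------

def _elementwise(a, fn, dfn) -> Tensor:
    a = as_tensor(a)
    out_data = fn(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * dfn(a.data, out_data))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    return _elementwise(a, np.exp, lambda x, y: y)


def log(a) -> Tensor:
    return _elementwise(a, np.log, lambda x, y: 1.0 / x)


def tanh(a) -> Tensor:
    return _elementwise(a, np.tanh, lambda x, y: 1.0 - y * y)


def cos(a) -> Tensor:
    return _elementwise(a, np.cos, lambda x, y: -np.sin(x))


def sin(a) -> Tensor:
    return _elementwise(a, np.sin, lambda x, y: np.cos(x))


def softplus(a) -> Tensor:
    return _elementwise(
        a,
        lambda x: np.logaddexp(0.0, x),
        lambda x, y: _special.expit(x),
    )


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """tanh-approximate GELU: 0.5 x (1 + tanh(sqrt(2/pi) (x + 0.044715 x^3)))."""
    a = as_tensor(a)
    x = a.data
    t = np.tanh(_GELU_C * (x + 0.044715 * x ** 3))
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        if a.requires_grad:
            du = _GELU_C * (1.0 + 3.0 * 0.044715 * x * x)
            a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du))

    return _make(out_data, (a,), backward)


def layer_norm(a, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale/shift (fused op)."""
    a = as_tensor(a)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, x.shape[-1]).sum(axis=0))
        if a.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (dxhat - m1 - xhat * m2))

    return _make(out_data, (a, gamma, beta), backward)


def wrap_angle(a) -> Tensor:
    """Wrap to (-pi, pi]; piecewise identity, so the gradient passes through."""
    return _elementwise(
        a,
        lambda x: -((-x + np.pi) % (2.0 * np.pi) - np.pi),
        lambda x, y: np.ones_like(x),
    )


def log_bessel_i0(a) -> Tensor:
    """log I0(x) computed stably via the exponentially scaled Bessel function."""
    return _elementwise(
        a,
        lambda x: np.log(_special.i0e(x)) + np.abs(x),
        lambda x, y: _special.i1e(x) / _special.i0e(x) * np.sign(x),
    )


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        if a.requires_grad:
            soft = np.exp(out_data)
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    mx = a.data.max(axis=axis, keepdims=True)
    out_keep = mx + np.log(np.exp(a.data - mx).sum(axis=axis, keepdims=True))
    out_data = out_keep if keepdims else np.squeeze(out_keep, axis=axis)

    def backward(g):
        if a.requires_grad:
            gk = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.exp(a.data - out_keep) * gk)

    return _make(out_data, (a,), backward)
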