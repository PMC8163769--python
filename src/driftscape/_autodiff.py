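"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed to express the potential network,
its analytic input-gradient (the drift), the Euler-Maruyama recursion, and
the training loss. First-order only: the drift is written out as an explicit
expression in the network weights (see ``potential.drift_expr``), so a single
reverse sweep yields exact parameter gradients of losses that depend on
simulated trajectories.

Gradients of non-smooth external quantities (the Sinkhorn divergence) enter
through :class:`ExternalGrad` nodes carrying precomputed cotangents.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph. ``value`` is a numpy array (or scalar)."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph construction -------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def bwd(g):
            _accum(self, _unbroadcast(g, self.value.shape))
            _accum(other, _unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def bwd(g):
            _accum(self, _unbroadcast(g * other.value, self.value.shape))
            _accum(other, _unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bwd(g):
            _accum(self, g @ other.value.T)
            _accum(other, self.value.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: _accum(self, g.T)
        return out

    def sum(self):
        out = Tensor(self.value.sum(), (self,))
        out._backward = lambda g: _accum(self, np.broadcast_to(g, self.value.shape).copy())
        return out

    def mean(self):
        return self.sum() / self.value.size

    def square(self):
        return self * self

    # ---- reverse sweep ------------------------------------------------------

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order = []
        seen = set()

        def topo(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                topo(p)
            order.append(node)

        topo(self)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(node: Tensor, g: np.ndarray):
    if node.grad is None:
        node.grad = np.array(g, dtype=float, copy=True)
    else:
        node.grad = node.grad + g


def softplus(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(np.logaddexp(0.0, x.value), (x,))
    out._backward = lambda g: _accum(x, g * expit(x.value))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = expit(x.value)
    out = Tensor(s, (x,))
    out._backward = lambda g: _accum(x, g * s * (1.0 - s))
    return out


def external_grad(x: Tensor, value: float, grad_x: np.ndarray) -> Tensor:
    """Scalar node whose value and gradient w.r.t. `x` were computed externally.

    Used for the Sinkhorn divergence, whose point-gradient is obtained from
    the converged transport plan (envelope theorem) rather than by tracing
    the fixed-point iterations.
    """
    out = Tensor(float(value), (x,))
    g_x = np.asarray(grad_x, dtype=float)
    out._backward = lambda g: _accum(x, float(g) * g_x)
    return out
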