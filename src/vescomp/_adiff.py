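"""Minimal reverse-mode automatic differentiation for triangle-mesh energies.

A tape-free graph of :class:`Var` nodes supporting exactly the operations the
discrete membrane energies need: elementwise arithmetic, square root, sums,
row gather/scatter, and 3-vector cross products.  Gradients are exact to
machine precision (validated against central finite differences in the test
suite).  Only first derivatives are provided; the shape optimizer pairs this
with limited-memory quasi-Newton updates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "constant", "gather", "scatter", "cross", "vsum", "sqrt", "grad"]


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum an upstream gradient over axes that numpy broadcasting introduced."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Var:
    """Node in the computation graph: a value plus a vector-Jacobian closure."""

    __slots__ = ("value", "parents", "vjp")

    def __init__(self, value, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents
        self.vjp = vjp

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(constant(other), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    @property
    def shape(self):
        return self.value.shape


def constant(value) -> Var:
    return Var(value)


def _wrap(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def add(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    sa, sb = a.value.shape, b.value.shape
    return Var(a.value + b.value, (a, b),
               lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)))


def mul(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    av, bv = a.value, b.value
    return Var(av * bv, (a, b),
               lambda g: (_unbroadcast(g * bv, av.shape), _unbroadcast(g * av, bv.shape)))


def div(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    av, bv = a.value, b.value
    return Var(av / bv, (a, b),
               lambda g: (_unbroadcast(g / bv, av.shape),
                          _unbroadcast(-g * av / (bv * bv), bv.shape)))


def power(a, p: float) -> Var:
    a = _wrap(a)
    av = a.value
    return Var(av ** p, (a,), lambda g: (g * p * av ** (p - 1.0),))


def sqrt(a) -> Var:
    a = _wrap(a)
    root = np.sqrt(a.value)
    return Var(root, (a,), lambda g: (g * 0.5 / root,))


def vsum(a, axis=None, keepdims=False) -> Var:
    a = _wrap(a)
    av = a.value
    out = av.sum(axis=axis, keepdims=keepdims)

    def back(g):
        g = np.asarray(g, float)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, av.shape).copy(),)

    return Var(out, (a,), back)


def gather(a, idx: np.ndarray) -> Var:
    """Row selection ``a[idx]`` along the first axis."""
    a = _wrap(a)
    av = a.value
    n = av.shape[0]

    def back(g):
        return (_scatter_value(idx, g, n),)

    return Var(av[idx], (a,), back)


def _scatter_value(idx: np.ndarray, contrib: np.ndarray, n: int) -> np.ndarray:
    contrib = np.asarray(contrib, float)
    if contrib.ndim == 1:
        return np.bincount(idx, weights=contrib, minlength=n)
    out = np.empty((n,) + contrib.shape[1:], dtype=float)
    flat = contrib.reshape(len(idx), -1)
    for c in range(flat.shape[1]):
        out.reshape(n, -1)[:, c] = np.bincount(idx, weights=flat[:, c], minlength=n)
    return out


def scatter(idx: np.ndarray, contrib, n: int) -> Var:
    """Sum rows of ``contrib`` into an ``(n, ...)`` array at positions ``idx``."""
    contrib = _wrap(contrib)
    return Var(_scatter_value(idx, contrib.value, n), (contrib,),
               lambda g: (g[idx],))


def expand_last(a) -> Var:
    """Append a trailing unit axis (for row-wise scaling of vector arrays)."""
    a = _wrap(a)
    return Var(a.value[..., None], (a,), lambda g: (g[..., 0],))


def embed(xfree, template: np.ndarray, idx: np.ndarray) -> Var:
    """Place the rows of ``xfree`` into a constant template at positions ``idx``."""
    xfree = _wrap(xfree)
    val = np.array(template, dtype=float, copy=True)
    val[idx] = xfree.value
    return Var(val, (xfree,), lambda g: (g[idx],))


def cross(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    av, bv = a.value, b.value
    return Var(np.cross(av, bv), (a, b),
               lambda g: (np.cross(bv, g), np.cross(g, av)))


def dot_rows(a, b) -> Var:
    """Per-row inner product of two (n, 3) arrays."""
    return vsum(mul(a, b), axis=-1)


def norm_rows(a) -> Var:
    return sqrt(dot_rows(a, a))


def grad(out: Var, leaf: Var) -> np.ndarray:
    """Gradient of the scalar ``out`` with respect to ``leaf`` by reverse sweep."""
    order: list[Var] = []
    seen: set[int] = set()
    stack = [(out, False)]
    while stack:  # iterative post-order DFS
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))

    grads: dict[int, np.ndarray] = {id(out): np.ones_like(out.value)}
    for node in reversed(order):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg
    return grads.get(id(leaf), np.zeros_like(leaf.value))
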