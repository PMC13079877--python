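"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The excess-Gibbs-energy model in this package is a *generating function*:
activity coefficients are composition derivatives of gE/(RT), excess
enthalpies are temperature derivatives, and the stability condition for
liquid-liquid demixing involves the second composition derivative of the
Gibbs energy of mixing.  Training in turn needs parameter gradients of all
of those quantities.  The engine here is therefore *closed under
differentiation*: every backward rule is itself expressed in the engine's
primitives, so ``grad`` can be applied to the output of ``grad`` (up to the
third mixed order used by the Gibbs stability loss).

Only the small set of primitives the package needs is implemented; arrays
are always float64 and broadcasting follows NumPy semantics.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit


class Tensor:
    """A NumPy array with an optional gradient tape behind it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # -- array-like surface -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
    rg = False
    for p in parents:
        if p.requires_grad:
            rg = True
            break
    out.requires_grad = rg
    if rg:
        out._parents = tuple(parents)
        out._vjp = vjp
    else:
        out._parents = ()
        out._vjp = None
    return out


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcasted cotangent back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra for i, s in enumerate(shape) if s == 1 and g.shape[i + extra] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=False)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- elementwise arithmetic ---------------------------------------------------

def add(a, b):
    if not isinstance(a, Tensor):
        a = Tensor(a)
    if not isinstance(b, Tensor):
        b = Tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    if not isinstance(a, Tensor):
        a = Tensor(a)
    if not isinstance(b, Tensor):
        b = Tensor(b)
    return _make(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)),
    )


def neg(a):
    if not isinstance(a, Tensor):
        a = Tensor(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b):
    if not isinstance(a, Tensor):
        a = Tensor(a)
    if not isinstance(b, Tensor):
        b = Tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b):
    a, b = astensor(a), astensor(b)
    return _make(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(div(g, b), a.shape),
            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def power(a, p: float):
    a = astensor(a)
    p = float(p)
    return _make(
        a.data ** p,
        (a,),
        lambda g: (mul(g, mul(Tensor(p), power(a, p - 1.0))),),
    )


def exp(a):
    a = astensor(a)
    out = _make(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a):
    a = astensor(a)
    return _make(np.log(a.data), (a,), lambda g: (div(g, a),))


def sigmoid(a):
    a = astensor(a)
    out = _make(_expit(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, sub(1.0, out))),)
    return out


def softplus(a):
    a = astensor(a)
    return _make(np.logaddexp(0.0, a.data), (a,), lambda g: (mul(g, sigmoid(a)),))


def tanh(a):
    a = astensor(a)
    out = _make(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, sub(1.0, mul(out, out))),)
    return out


def silu(a):
    """Sigmoid Linear Unit, x * sigmoid(x)."""
    a = astensor(a)
    return mul(a, sigmoid(a))


def where(cond, a, b):
    """Select with a *constant* boolean mask (no gradient through cond)."""
    cond = np.asarray(cond, dtype=bool)
    a, b = astensor(a), astensor(b)
    return _make(
        np.where(cond, a.data, b.data),
        (a, b),
        lambda g: (
            _unbroadcast(where(cond, g, Tensor(0.0)), a.shape),
            _unbroadcast(where(cond, Tensor(0.0), g), b.shape),
        ),
    )


def absolute(a):
    a = astensor(a)
    return where(a.data >= 0.0, a, neg(a))


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    return where(a.data >= b.data, a, b)


# -- shape manipulation -------------------------------------------------------

def reshape(a, shape):
    a = astensor(a)
    old = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),))


def transpose(a):
    a = astensor(a)
    return _make(a.data.T, (a,), lambda g: (transpose(g),))


def broadcast_to(a, shape):
    a = astensor(a)
    old = a.shape
    return _make(
        np.broadcast_to(a.data, shape),
        (a,),
        lambda g: (_unbroadcast(g, old),),
    )


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    kept = tuple(1 if i in axes else s for i, s in enumerate(in_shape))

    def vjp(g):
        return (broadcast_to(reshape(g, kept), in_shape),)

    return _make(np.sum(a.data, axis=axes, keepdims=keepdims), (a,), vjp)


def tmax(a, axis=None, keepdims=False):
    """Maximum along an axis; subgradient routed to the first argmax."""
    a = astensor(a)
    if axis is None:
        flat_idx = int(np.argmax(a.data))
        mask = np.zeros(a.shape)
        mask.ravel()[flat_idx] = 1.0
        data = np.max(a.data, keepdims=keepdims)
        kept = (1,) * a.ndim
    else:
        ax = axis % a.ndim
        idx = np.expand_dims(np.argmax(a.data, axis=ax), ax)
        mask = np.zeros(a.shape)
        np.put_along_axis(mask, idx, 1.0, axis=ax)
        data = np.max(a.data, axis=ax, keepdims=keepdims)
        kept = tuple(1 if i == ax else s for i, s in enumerate(a.shape))

    def vjp(g):
        return (mul(broadcast_to(reshape(g, kept), a.shape), Tensor(mask)),)

    return _make(data, (a,), vjp)


def tmin(a, axis=None, keepdims=False):
    return neg(tmax(neg(a), axis=axis, keepdims=keepdims))


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def concat(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            key = tuple(
                slice(lo, hi) if i == (axis % t.ndim) else slice(None)
                for i in range(t.ndim)
            )
            outs.append(getitem(g, key))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def getitem(a, key):
    a = astensor(a)
    shape = a.shape
    return _make(a.data[key], (a,), lambda g: (scatter(g, shape, key),))


def scatter(g, shape, key):
    """Place ``g`` into a zero array of ``shape`` at ``key`` (basic indexing)."""
    g = astensor(g)
    data = np.zeros(shape)
    data[key] = g.data
    return _make(data, (g,), lambda c: (getitem(c, key),))


# -- differentiation ----------------------------------------------------------

def grad(output: Tensor, inputs, seed: Tensor | None = None):
    """Cotangents of ``output`` w.r.t. ``inputs``.

    ``seed`` defaults to ones with the shape of ``output`` (so a scalar
    output yields ordinary gradients, and a vector output yields the
    gradient of its sum — which for elementwise-independent batches is the
    per-element derivative).  The returned tensors carry their own tape, so
    they can be differentiated again.
    """
    inputs = list(inputs)
    if seed is None:
        seed = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    cot: dict[int, Tensor] = {id(output): seed}
    for node in reversed(topo):
        g = cot.get(id(node))
        if g is None or node._vjp is None:
            continue
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            prev = cot.get(id(p))
            cot[id(p)] = pg if prev is None else add(prev, pg)

    out = []
    for t in inputs:
        g = cot.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros(t.shape)))
    return out
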