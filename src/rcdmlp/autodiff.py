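"""Minimal reverse-mode automatic differentiation on numpy arrays.

The correction models need exact analytic forces (-dE/dx) and a training loss
that penalizes force errors, whose parameter gradient involves second
derivatives d2E/(dx dtheta).  To support that, every backward rule here is
itself written in terms of traced ops, so ``grad(..., create_graph=True)``
yields a differentiable graph and grad-of-grad works.

Only the op set the models need is implemented: elementwise arithmetic and
transcendentals, axis reductions, two-operand einsum, gather/scatter along
axis 0, and stacking.  Shapes broadcast like numpy; gradients are
un-broadcast by summation.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "power",
    "exp",
    "log",
    "sin",
    "cos",
    "sqrt",
    "tanh",
    "sigmoid",
    "silu",
    "tsum",
    "reshape",
    "transpose",
    "einsum",
    "take0",
    "scatter_add0",
    "stack_last",
    "norm_lastdim",
]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents: tuple = ()
        self.vjp = None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # operator sugar
    def __add__(self, o):
        return add(self, o)

    __radd__ = __add__

    def __mul__(self, o):
        return mul(self, o)

    __rmul__ = __mul__

    def __sub__(self, o):
        return sub(self, o)

    def __rsub__(self, o):
        return sub(o, self)

    def __truediv__(self, o):
        return div(self, o)

    def __rtruediv__(self, o):
        return div(o, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp) -> Tensor:
    t = Tensor(data)
    if _GRAD_ENABLED[-1]:
        t.parents = tuple(parents)
        t.vjp = vjp
    return t


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum g over axes that were broadcast to reach g.shape from shape."""
    if g.shape == tuple(shape):
        return g
    extra = len(g.shape) - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------- arithmetic


def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)

    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(mul(g, div(a, mul(b, b)))), b.shape)
        return ga, gb

    return _make(a.data / b.data, (a, b), vjp)


def neg(a) -> Tensor:
    a = tensor(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def power(a, p: float) -> Tensor:
    a = tensor(a)
    p = float(p)
    return _make(a.data**p, (a,), lambda g: (mul(g, mul(p, power(a, p - 1.0))),))


def exp(a) -> Tensor:
    a = tensor(a)
    return _make(np.exp(a.data), (a,), lambda g: (mul(g, exp(a)),))


def log(a) -> Tensor:
    a = tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (div(g, a),))


def sin(a) -> Tensor:
    a = tensor(a)
    return _make(np.sin(a.data), (a,), lambda g: (mul(g, cos(a)),))


def cos(a) -> Tensor:
    a = tensor(a)
    return _make(np.cos(a.data), (a,), lambda g: (neg(mul(g, sin(a))),))


def sqrt(a) -> Tensor:
    a = tensor(a)
    return _make(np.sqrt(a.data), (a,), lambda g: (div(mul(0.5, g), sqrt(a)),))


def tanh(a) -> Tensor:
    a = tensor(a)

    def vjp(g):
        t = tanh(a)
        return (mul(g, sub(1.0, mul(t, t))),)

    return _make(np.tanh(a.data), (a,), vjp)


def sigmoid(a) -> Tensor:
    a = tensor(a)

    def vjp(g):
        s = sigmoid(a)
        return (mul(g, mul(s, sub(1.0, s))),)

    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), vjp)


def silu(a) -> Tensor:
    """Sigmoid linear unit x * sigma(x)."""
    a = tensor(a)
    return mul(a, sigmoid(a))


# ---------------------------------------------------------------- structural


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = tensor(a)
    out = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            shape = list(out.shape)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                shape.insert(ax, 1)
            gd = reshape(gd, tuple(shape))
        ones = Tensor(np.ones(a.shape))
        return (mul(gd, ones),)

    return _make(out, (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = tensor(a)
    shape = tuple(shape)
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),))


def transpose(a, axes) -> Tensor:
    a = tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def einsum(subscripts: str, a, b) -> Tensor:
    """Two-operand einsum.  Every index of each operand must appear in the
    output or the other operand (no internal diagonals/self-sums)."""
    a, b = tensor(a), tensor(b)
    lhs, out_sub = subscripts.replace(" ", "").split("->")
    sub_a, sub_b = lhs.split(",")
    for s, other in ((sub_a, sub_b), (sub_b, sub_a)):
        if len(set(s)) != len(s):
            raise ValueError(f"repeated index within one operand: {subscripts}")
        if not set(s) <= set(out_sub) | set(other):
            raise ValueError(f"unsupported einsum for autodiff: {subscripts}")

    def vjp(g):
        ga = gb = None
        if a.parents or a.requires_grad:
            ga = einsum(f"{out_sub},{sub_b}->{sub_a}", g, b)
        if b.parents or b.requires_grad:
            gb = einsum(f"{out_sub},{sub_a}->{sub_b}", g, a)
        return ga, gb

    return _make(np.einsum(subscripts, a.data, b.data, optimize=True), (a, b), vjp)


def take0(a, idx) -> Tensor:
    """Gather rows along axis 0: out[k] = a[idx[k]]."""
    a = tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    n = a.shape[0]
    return _make(a.data[idx], (a,), lambda g: (scatter_add0(g, idx, n),))


_ONEHOT_CACHE: dict = {}


def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
    key = (n, idx.tobytes())
    got = _ONEHOT_CACHE.get(key)
    if got is None:
        got = np.zeros((n, idx.size))
        got[idx, np.arange(idx.size)] = 1.0
        if len(_ONEHOT_CACHE) > 64:
            _ONEHOT_CACHE.clear()
        _ONEHOT_CACHE[key] = got
    return got


def scatter_add0(a, idx, n: int) -> Tensor:
    """Scatter-add rows along axis 0: out[j] = sum_{k: idx[k]=j} a[k]."""
    a = tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    flat = a.data.reshape(idx.size, -1)
    out = (_onehot(idx, n) @ flat).reshape((n,) + a.shape[1:])
    return _make(out, (a,), lambda g: (take0(g, idx),))


def stack_last(tensors) -> Tensor:
    """Stack along a new trailing axis."""
    ts = [tensor(t) for t in tensors]
    out = np.stack([t.data for t in ts], axis=-1)

    def vjp(g):
        return tuple(_slice_last(g, i) for i in range(len(ts)))

    return _make(out, tuple(ts), vjp)


def _slice_last(a: Tensor, i: int) -> Tensor:
    a = tensor(a)
    k = a.shape[-1]

    def vjp(g):
        # re-embed the slice at position i of the trailing axis
        parts = [g if j == i else Tensor(np.zeros(g.shape)) for j in range(k)]
        return (stack_last(parts),)

    return _make(a.data[..., i], (a,), vjp)


def norm_lastdim(a, eps: float = 0.0) -> Tensor:
    """Euclidean norm over the trailing axis."""
    a = tensor(a)
    return sqrt(tsum(mul(a, a), axis=-1) + eps)


# ---------------------------------------------------------------- grad


def _toposort(root: Tensor, needed: set) -> list:
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or id(node) not in needed:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order


def _needed_set(root: Tensor, inputs) -> set:
    """Ids of nodes on a path from any input to the root."""
    input_ids = {id(x) for x in inputs}
    memo: dict[int, bool] = {}

    def visit(start: Tensor) -> bool:
        stack = [(start, 0)]
        while stack:
            node, state = stack.pop()
            if state == 0:
                if id(node) in memo:
                    continue
                if id(node) in input_ids:
                    memo[id(node)] = True
                    continue
                stack.append((node, 1))
                for p in node.parents:
                    if id(p) not in memo:
                        stack.append((p, 0))
            else:
                memo[id(node)] = any(memo.get(id(p), False) for p in node.parents)
        return memo.get(id(start), False)

    visit(root)
    return {k for k, v in memo.items() if v} | {id(root)}


def grad(output: Tensor, inputs, create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar output w.r.t. each input tensor.

    With ``create_graph=True`` the returned gradients are themselves traced,
    so they can be differentiated again (used by the force-matching loss).
    """
    if output.data.size != 1:
        raise ValueError("grad requires a scalar output")
    needed = _needed_set(output, inputs)
    order = _toposort(output, needed)
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    ctx = _GRAD_ENABLED
    ctx.append(bool(create_graph))
    try:
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None or node.vjp is None:
                continue
            contribs = node.vjp(g)
            for p, c in zip(node.parents, contribs):
                if c is None or id(p) not in needed:
                    continue
                prev = grads.get(id(p))
                grads[id(p)] = c if prev is None else add(prev, c)
    finally:
        ctx.pop()
    out = []
    for x in inputs:
        gx = grads.get(id(x))
        out.append(gx if gx is not None else Tensor(np.zeros(x.shape)))
    return out
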