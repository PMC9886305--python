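"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine sized for desk-scale models
(embedding dims of order 10-100, sequences of order 10-100 tokens).
Every backward rule is itself expressed with :class:`Tensor` operations,
so differentiating through a gradient (as second-order meta-learning
requires) works without special casing: call :func:`grad` with
``create_graph=True`` and differentiate the result again.

Arrays are float64 throughout; model sizes here never make that a cost
worth trading for reproducibility.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (used inside first-order
    backward passes and pure evaluation)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _tracing() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """An ndarray plus the tape edges needed to backpropagate through it."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        # sequence of (parent_tensor, vjp) pairs; vjp maps the upstream
        # gradient Tensor to this parent's gradient contribution Tensor
        self._parents = _parents

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    if _tracing() and any(p.requires_grad for p, _ in parents):
        return Tensor(data, requires_grad=True,
                      _parents=tuple((p, f) for p, f in parents if p.requires_grad))
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tensor_sum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tensor_sum(g, axis=axes, keepdims=True)
    return reshape(g, tuple(shape))


# ---- primitive operations ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data + b.data,
                 [(a, lambda g: _unbroadcast(g, a.shape)),
                  (b, lambda g: _unbroadcast(g, b.shape))])


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data * b.data,
                 [(a, lambda g: _unbroadcast(mul(g, b.detach() if not b.requires_grad else b), a.shape)),
                  (b, lambda g: _unbroadcast(mul(g, a.detach() if not a.requires_grad else a), b.shape))])


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    exponent = float(exponent)
    out = a.data ** exponent

    def vjp(g):
        return mul(g, mul(power(a, exponent - 1.0), exponent))

    return _make(out, [(a, vjp)])


def _mT(a: "Tensor") -> "Tensor":
    """Transpose of the last two axes (matrix transpose of a stack)."""
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >=2-d operands")
    return _make(a.data @ b.data,
                 [(a, lambda g: matmul(g, _mT(b))),
                  (b, lambda g: matmul(_mT(a), g))])


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    inv = None if axes is None else tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes),
                 [(a, lambda g: transpose(g, inv))])


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g, lo=lo, hi=hi, axis=axis):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return take(g, tuple(sl))

        parents.append((t, vjp))
    return _make(np.concatenate([t.data for t in tensors], axis=axis), parents)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out = np.exp(a.data)
    res = _make(out, [(a, lambda g: mul(g, res if res.requires_grad else Tensor(out)))])
    return res


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = np.tanh(a.data)
    res = _make(out, [(a, lambda g: mul(g, 1.0 - power(res, 2.0) if res.requires_grad else Tensor(1.0 - out * out)))])
    return res


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    res = _make(out, [(a, lambda g: mul(g, mul(res, 1.0 - res) if res.requires_grad else Tensor(out * (1.0 - out))))])
    return res


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    return _make(a.data * mask, [(a, lambda g: mul(g, mask))])


def tensor_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    shape = a.shape

    def vjp(g):
        if axis is None:
            return mul(reshape(g, (1,) * len(shape)), np.ones(shape))
        ax = axis if isinstance(axis, tuple) else (axis,)
        ax = tuple(i % len(shape) for i in ax)
        if not keepdims:
            kshape = tuple(1 if i in ax else n for i, n in enumerate(shape))
            g = reshape(g, kshape)
        return mul(g, np.ones(shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def tensor_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod([a.shape[i % a.ndim] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tensor_max(a, axis=None, keepdims=False) -> Tensor:
    """Max reduction; ties share the (sub)gradient equally."""
    a = _as_tensor(a)
    out = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)
    shape = a.shape

    def vjp(g):
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % len(shape) for i in ax)
            kshape = tuple(1 if i in ax else n for i, n in enumerate(shape))
            g = reshape(g, kshape)
        elif axis is None and not keepdims:
            g = reshape(g, (1,) * len(shape))
        return mul(g, mask)

    data = out if keepdims else (out.reshape(()) if axis is None else np.squeeze(out, axis=axis))
    return _make(data, [(a, vjp)])


def take(a, idx) -> Tensor:
    """Indexing/gather; adjoint is scatter-add into the source shape."""
    a = _as_tensor(a)
    shape = a.shape
    return _make(a.data[idx], [(a, lambda g: scatter_add(g, idx, shape))])


def scatter_add(g, idx, shape) -> Tensor:
    g = _as_tensor(g)

    def fwd(gd):
        out = np.zeros(shape)
        np.add.at(out, idx, gd)
        return out

    return _make(fwd(g.data), [(g, lambda gg: take(gg, idx))])


def where(cond: np.ndarray, a, b) -> Tensor:
    cond = np.asarray(cond, dtype=bool)
    a, b = _as_tensor(a), _as_tensor(b)
    return add(mul(a, cond.astype(np.float64)), mul(b, (~cond).astype(np.float64)))


# ---- composites ----------------------------------------------------------

def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = a - tensor_max(a, axis=axis, keepdims=True).detach()
    return shift - log(tensor_sum(exp(shift), axis=axis, keepdims=True))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


def cross_entropy(logits: Tensor, labels: np.ndarray, axis: int = -1) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``.

    ``labels`` has the shape of ``logits`` minus the class axis.
    """
    labels = np.asarray(labels, dtype=np.intp)
    logp = log_softmax(logits, axis=axis)
    if axis != -1 and axis != logits.ndim - 1:
        raise ValueError("class axis must be last")
    flat = reshape(logp, (-1, logits.shape[-1]))
    picked = take(flat, (np.arange(labels.size), labels.ravel()))
    return -tensor_mean(picked)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean BCE: max(z,0) - z*y + log(1+exp(-|z|))."""
    t = np.asarray(targets, dtype=np.float64)
    pos = relu(logits)
    absz = relu(logits) + relu(-logits)
    return tensor_mean(pos - mul(logits, t) + log(1.0 + exp(-absz)))


# ---- backpropagation -----------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            stack.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, inputs: Iterable[Tensor], create_graph: bool = False):
    """Gradients of scalar ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own tape
    and can be differentiated again (needed for second-order meta-updates).
    Inputs not reachable from the output get zero gradients.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    inputs = list(inputs)
    input_ids = {id(t) for t in inputs}
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_toposort(output)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._parents:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else add(prev, contrib)
            if id(node) in input_ids:
                grads[id(node)] = g
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out
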