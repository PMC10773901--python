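"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to train the conditional WGAN-GP and the compact CNN
classifier in this package. Vector-Jacobian products are themselves built
from differentiable primitives, so gradients of gradients (double backprop,
required by the WGAN gradient penalty) work without special casing: calling
:func:`grad` on an expression that already contains gradient tensors simply
extends the graph.

Only the primitives the package needs are provided; all are dense arrays of
a single module-wide dtype (``DTYPE``).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

#: computation dtype of the engine; single precision is ample for GAN/CNN
#: training and halves memory traffic in the im2col convolutions
DTYPE = np.float32

__all__ = [
    "Tensor",
    "grad",
    "add",
    "mul",
    "neg",
    "pow_",
    "exp",
    "log",
    "tanh",
    "matmul",
    "reshape",
    "transpose",
    "sum_",
    "mean_",
    "broadcast_to",
    "take",
    "put",
    "leaky_relu",
    "concat",
]


class Tensor:
    """An n-d array plus the graph edges needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "parents", "vjps")
    __array_priority__ = 100.0

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        vjps: tuple[Callable[["Tensor"], "Tensor"], ...] = (),
    ):
        self.data = np.asarray(data, dtype=DTYPE) if not isinstance(data, np.ndarray) else data
        if self.data.dtype != DTYPE:
            self.data = self.data.astype(DTYPE)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjps = vjps

    # -- ergonomics ---------------------------------------------------------
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

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(_as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, float(p))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _node(data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    parents = tuple(parents)
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjps=tuple(vjps))
    return Tensor(data)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcasted gradient back to ``shape``."""
    if g.shape == shape:
        return g
    # sum the leading added axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)), keepdims=False)
    # sum axes that were broadcast from 1
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- primitives --------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data
    return _node(out, (a, b), (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)))


def neg(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data
    return _node(
        out,
        (a, b),
        (lambda g: _unbroadcast(mul(g, b), a.shape), lambda g: _unbroadcast(mul(g, a), b.shape)),
    )


def pow_(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    out = a.data**p
    return _node(out, (a,), (lambda g: mul(g, mul(Tensor(p), pow_(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g, _out=None):
        return mul(g, exp(a))

    return _node(out_data, (a,), (vjp,))


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), (lambda g: mul(g, pow_(a, -1.0)),))


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(np.tanh(a.data), (a,), (lambda g: mul(g, add(Tensor(1.0), neg(pow_(tanh(a), 2.0)))),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out = a.data @ b.data
    return _node(
        out,
        (a, b),
        (
            lambda g: matmul(g, transpose(b, (1, 0))),
            lambda g: matmul(transpose(a, (1, 0)), g),
        ),
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(int(s) for s in shape)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), (lambda g: reshape(g, old),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(int(x) for x in axes)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),))


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.shape
    if axis is None:
        kd_shape = (1,) * a.ndim
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        ax = tuple(i % a.ndim for i in ax)
        kd_shape = tuple(1 if i in ax else s for i, s in enumerate(in_shape))

    def vjp(g):
        return broadcast_to(reshape(g, kd_shape), in_shape)

    return _node(np.asarray(out), (a,), (vjp,))


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(int(s) for s in shape)
    old = a.shape
    out = np.broadcast_to(a.data, shape).copy()
    return _node(out, (a,), (lambda g: _unbroadcast(g, old),))


def take(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``a.reshape(-1)[idx]``; output has the shape of ``idx``."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    size, shape = a.size, a.shape
    out = a.data.reshape(-1)[idx]

    def vjp(g):
        return reshape(put(g, idx, size), shape)

    return _node(out, (a,), (vjp,))


def put(vals: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Scatter-add ``vals`` into a flat zero vector of length ``size``."""
    vals = _as_tensor(vals)
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros(int(size), dtype=DTYPE)
    np.add.at(out, idx.reshape(-1), vals.data.reshape(-1))
    vshape = vals.shape

    def vjp(g):
        return reshape(take(g, idx), vshape)

    return _node(out, (vals,), (vjp,))


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    # the slope mask is piecewise constant, so it is treated as data in the
    # vjp; second derivatives through it are zero almost everywhere
    factor = np.where(a.data > 0, 1.0, float(alpha))
    return _node(a.data * factor, (a,), (lambda g: mul(g, Tensor(factor)),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` (composite: scatter each part into place)."""
    tensors = [_as_tensor(t) for t in tensors]
    datas = [t.data for t in tensors]
    out_shape = list(datas[0].shape)
    axis = axis % len(out_shape)
    out_shape[axis] = sum(d.shape[axis] for d in datas)
    out_shape = tuple(out_shape)
    size = int(np.prod(out_shape))
    flat_pos = np.arange(size).reshape(out_shape)
    pieces = []
    offset = 0
    for t in tensors:
        n = t.shape[axis]
        sl = [slice(None)] * len(out_shape)
        sl[axis] = slice(offset, offset + n)
        idx = flat_pos[tuple(sl)]
        pieces.append(reshape(put(t, idx, size), out_shape))
        offset += n
    out = pieces[0]
    for p in pieces[1:]:
        out = add(out, p)
    return out


# -- reverse mode ------------------------------------------------------------


def grad(output: Tensor, wrt: Iterable[Tensor]) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    The returned gradients carry their own graphs, so they can be
    differentiated again (double backprop).
    """
    wrt = list(wrt)
    if output.size != 1:
        raise ValueError("grad expects a scalar output")

    # topological order over the subgraph that requires grad
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape, dtype=DTYPE))}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if not parent.requires_grad:
                continue
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else add(prev, contrib)
        if node in wrt:  # keep gradients requested by the caller
            grads[id(node)] = g
    out = []
    for w in wrt:
        g = grads.get(id(w))
        out.append(g if g is not None else Tensor(np.zeros(w.shape)))
    return out
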