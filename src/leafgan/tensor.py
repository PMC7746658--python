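"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tensor engine sufficient for training convolutional
GANs and classifiers on a CPU.  Every vector-Jacobian product is itself
written in terms of engine ops, so ``grad(..., create_graph=True)`` yields a
differentiable graph and second-order quantities — in particular the
gradient penalty of a Wasserstein critic — are computed by exact double
backpropagation rather than finite differences.

Conventions
-----------
* Arrays are float64 throughout; image batches are NHWC.
* ``grad`` is functional: it returns cotangents and never mutates tensors.
* Broadcasting follows NumPy; cotangents are summed back to operand shape.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "grad",
    "add", "mul", "div", "neg", "matmul", "pow_const", "exp", "log", "sqrt",
    "tanh", "tsum", "tmean", "reshape", "transpose2d", "pad2d", "crop2d",
    "im2col", "col2im", "upsample_nearest", "maxpool2x2", "gather_rows",
    "relu", "leaky_relu", "sigmoid", "softmax", "logsumexp",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (used for plain evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An n-d array plus the bookkeeping needed for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, vjp: cotangent Tensor -> cotangent Tensor)
        self._parents = list(_parents) if _parents else []

    # -- conveniences ------------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return np.array(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, k):
        return pow_const(self, float(k))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*pairs) -> list:
    """Keep only parent links that can propagate gradient."""
    if not _grad_enabled:
        return []
    return [(p, fn) for p, fn in pairs if p.requires_grad or p._parents]


def _make(data, *pairs) -> Tensor:
    parents = _track(*pairs)
    rg = any(p.requires_grad or p._parents for p, _ in parents)
    return Tensor(data, requires_grad=rg, _parents=parents)


def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast cotangent back to the operand's shape."""
    if g.shape == shape:
        return g
    # sum over leading broadcast axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# -- arithmetic primitives -------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data,
                 (a, lambda g: _sum_to(g, a.shape)),
                 (b, lambda g: _sum_to(g, b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data,
                 (a, lambda g: _sum_to(mul(g, b), a.shape)),
                 (b, lambda g: _sum_to(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data,
                 (a, lambda g: _sum_to(div(g, b), a.shape)),
                 (b, lambda g: _sum_to(neg(div(mul(g, a), mul(b, b))), b.shape)))


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a, lambda g: neg(g)))


def pow_const(a: Tensor, k: float) -> Tensor:
    a = as_tensor(a)
    return _make(a.data ** k,
                 (a, lambda g: mul(g, mul(Tensor(k), pow_const(a, k - 1.0)))))


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a, lambda g: mul(g, out)))
    return out


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a, lambda g: div(g, a)))


def sqrt(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = _make(np.sqrt(a.data), (a, lambda g: div(g, mul(Tensor(2.0), out))))
    return out


def tanh(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = _make(np.tanh(a.data),
                (a, lambda g: mul(g, add(Tensor(1.0), neg(mul(out, out))))))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul expects 2-D operands")
    return _make(a.data @ b.data,
                 (a, lambda g: matmul(g, transpose2d(b))),
                 (b, lambda g: matmul(transpose2d(a), g)))


def transpose2d(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.T, (a, lambda g: transpose2d(g)))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.shape

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(ax % len(shape) for ax in axes)
            kshape = tuple(1 if i in axes else n for i, n in enumerate(shape))
            gd = reshape(gd, kshape)
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * len(shape))
        # broadcast up via multiplication with ones
        return mul(gd, Tensor(np.ones(shape)))

    return _make(data, (a, vjp))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.shape
    return _make(a.data.reshape(shape), (a, lambda g: reshape(g, orig)))


# -- structural primitives for convolutions --------------------------------

def pad2d(a: Tensor, pad: tuple) -> Tensor:
    """Zero-pad an NHWC batch; ``pad = ((top, bottom), (left, right))``."""
    a = as_tensor(a)
    (pt, pb), (pl, pr) = pad
    data = np.pad(a.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    return _make(data, (a, lambda g: crop2d(g, pad)))


def crop2d(a: Tensor, pad: tuple) -> Tensor:
    """Inverse of :func:`pad2d`: drop a zero-pad margin."""
    a = as_tensor(a)
    (pt, pb), (pl, pr) = pad
    H, W = a.shape[1], a.shape[2]
    data = a.data[:, pt:H - pb or None, pl:W - pr or None, :]
    return _make(data, (a, lambda g: pad2d(g, pad)))


def im2col(a: Tensor, ksize: int, stride: int) -> Tensor:
    """Extract dense k×k patches from an NHWC batch.

    Output shape ``(N, OH, OW, k*k*C)``; the inverse (scatter-add) is
    :func:`col2im`, and each is the other's vector-Jacobian product, which is
    what makes convolutions twice-differentiable here.
    """
    a = as_tensor(a)
    N, H, W, C = a.shape
    OH = (H - ksize) // stride + 1
    OW = (W - ksize) // stride + 1
    cols = np.empty((N, OH, OW, ksize * ksize, C), dtype=a.data.dtype)
    for i in range(ksize):
        for j in range(ksize):
            cols[:, :, :, i * ksize + j, :] = \
                a.data[:, i:i + stride * OH:stride, j:j + stride * OW:stride, :]
    data = cols.reshape(N, OH, OW, ksize * ksize * C)
    shape = (H, W)
    return _make(data, (a, lambda g: col2im(g, shape, ksize, stride, C)))


def col2im(a: Tensor, hw: tuple, ksize: int, stride: int, channels: int) -> Tensor:
    """Scatter-add patch columns back onto an image grid (adjoint of im2col)."""
    a = as_tensor(a)
    H, W = hw
    N, OH, OW, _ = a.shape
    cols = a.data.reshape(N, OH, OW, ksize * ksize, channels)
    out = np.zeros((N, H, W, channels), dtype=a.data.dtype)
    for i in range(ksize):
        for j in range(ksize):
            out[:, i:i + stride * OH:stride, j:j + stride * OW:stride, :] += \
                cols[:, :, :, i * ksize + j, :]
    return _make(out, (a, lambda g: im2col(g, ksize, stride)))


def upsample_nearest(a: Tensor, factor: int = 2) -> Tensor:
    a = as_tensor(a)
    data = a.data.repeat(factor, axis=1).repeat(factor, axis=2)

    def vjp(g):
        N, H2, W2, C = g.shape
        gg = reshape(g, (N, H2 // factor, factor, W2 // factor, factor, C))
        return tsum(gg, axis=(2, 4))

    return _make(data, (a, vjp))


def maxpool2x2(a: Tensor) -> Tensor:
    """2×2 max pooling, stride 2; ties resolve to the first position."""
    a = as_tensor(a)
    N, H, W, C = a.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    blocks = a.data.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    flat = blocks.reshape(N, H // 2, W // 2, 4, C)
    idx = flat.argmax(axis=3)                      # first max wins
    data = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    # constant 0/1 winner mask at input resolution
    onehot = (idx[:, :, :, None, :] == np.arange(4)[None, None, None, :, None])
    mask = onehot.astype(np.float64).reshape(N, H // 2, W // 2, 2, 2, C) \
        .transpose(0, 1, 3, 2, 4, 5).reshape(N, H, W, C)
    mask_t = Tensor(mask)

    def vjp(g):
        return mul(upsample_nearest(g, 2), mask_t)

    return _make(data, (a, vjp))


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``table[indices]`` with scatter-add adjoint (embeddings)."""
    table = as_tensor(table)
    idx = np.asarray(indices, dtype=np.int64)
    nrows = table.shape[0]

    def vjp(g):
        return scatter_rows(g, idx, nrows)

    return _make(table.data[idx], (table, vjp))


def scatter_rows(a: Tensor, indices: np.ndarray, nrows: int) -> Tensor:
    a = as_tensor(a)
    out = np.zeros((nrows,) + a.shape[1:], dtype=a.data.dtype)
    np.add.at(out, indices, a.data)
    return _make(out, (a, lambda g: gather_rows(g, indices)))


# -- composed non-linearities ----------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return mul(a, mask)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    scale = Tensor(mask + alpha * (1.0 - mask))
    return mul(a, scale)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return div(Tensor(1.0), add(Tensor(1.0), exp(neg(a))))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant; exact
    e = exp(add(a, neg(shift)))
    return div(e, tsum(e, axis=axis, keepdims=True))


def logsumexp(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    s = log(tsum(exp(add(a, neg(shift))), axis=axis, keepdims=True))
    return add(s, shift)


# -- reverse-mode driver ---------------------------------------------------

def _topo(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(output: Tensor, inputs: Iterable[Tensor],
         create_graph: bool = False) -> list:
    """Cotangents of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph, so
    they can be differentiated again (double backprop).
    """
    inputs = list(inputs)
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    cot: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}
    with ctx:
        for node in reversed(_topo(output)):
            g = cot.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = pg if prev is None else add(prev, pg)
            if any(node is x for x in inputs):
                cot[id(node)] = g  # keep requested leaves
    out = []
    for x in inputs:
        g = cot.get(id(x))
        if g is None:
            g = Tensor(np.zeros(x.shape))
        out.append(g)
    return out
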