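"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in this package is small enough (three residual blocks per
branch, one attention block, two dense layers) that a compact define-by-run
tape over numpy is sufficient: every op records its parents and a closure
that maps the output gradient to parent gradients, and :meth:`Tensor.backward`
walks the tape in reverse topological order.

All arrays are float32 NHWC unless noted.  Broadcasting follows numpy rules;
gradients of broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- reverse pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; the graph can exceed recursion limits
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_ensure(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, e):
        return power(self, e)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def power(a, e: float) -> Tensor:
    a = _ensure(a)
    out_data = a.data ** e

    def backward(g):
        a._accum(g * (e * a.data ** (e - 1.0)))

    return Tensor._from_op(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        if a.ndim == 1:  # vector @ matrix collapses an axis
            ga = ga.reshape(a.shape)
        if b.ndim == 1:
            gb = gb.reshape(b.shape)
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
        a._accum(np.broadcast_to(g, a.shape).astype(DTYPE))

    return Tensor._from_op(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return Tensor._from_op(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _ensure(a)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accum(g.transpose(inv))

    return Tensor._from_op(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._from_op(out_data, tensors, backward)


def relu(a) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accum(g * mask)

    return Tensor._from_op(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _ensure(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out_data[~pos] = ez / (1.0 + ez)

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _ensure(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return Tensor._from_op(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _ensure(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return Tensor._from_op(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the unclamped region."""
    a = _ensure(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accum(g * mask)

    return Tensor._from_op(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _ensure(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    s = ez / ez.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return Tensor._from_op(s, (a,), backward)


def amax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; gradient routes to the (first) argmax."""
    a = _ensure(a)
    idx = a.data.argmax(axis=axis, keepdims=True)
    out_data = np.take_along_axis(a.data, idx, axis=axis)
    if not keepdims:
        out_data = out_data.squeeze(axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, g, axis=axis)
        a._accum(ga)

    return Tensor._from_op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# spatial primitives (NHWC)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation.

    ``x``: (N, H, W, Cin); ``w``: (KH, KW, Cin, Cout); ``b``: (Cout,).
    Implemented as im2col + one GEMM; the column buffer is kept for the
    backward pass (dW = cols.T @ g, dX = scatter of g @ W.T).
    """
    x, w = _ensure(x), _ensure(w)
    b = _ensure(b) if b is not None else None
    N, H, W, Cin = x.shape
    KH, KW, Cin2, Cout = w.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, kernel {Cin2}")
    OH = (H + 2 * padding - KH) // stride + 1
    OW = (W + 2 * padding - KW) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    else:
        xp = x.data
    # (N, OH, OW, C, KH, KW) window view -> (N*OH*OW, KH*KW*C) columns
    win = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        N * OH * OW, KH * KW * Cin)
    wmat = w.data.reshape(KH * KW * Cin, Cout)
    out = (cols @ wmat).reshape(N, OH, OW, Cout)
    if b is not None:
        out += b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gflat = g.reshape(-1, Cout)
        if b is not None:
            b._accum(gflat.sum(axis=0))
        if w.requires_grad:
            w._accum((cols.T @ gflat).reshape(w.shape))
        if x.requires_grad:
            dcols = (gflat @ wmat.T).reshape(N, OH, OW, KH, KW, Cin)
            dxp = np.zeros_like(xp)
            for ki in range(KH):
                for kj in range(KW):
                    dxp[:, ki:ki + stride * OH:stride,
                        kj:kj + stride * OW:stride, :] += dcols[:, :, :, ki, kj, :]
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding, :]
            x._accum(dxp)

    return Tensor._from_op(out, parents, backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2; gradient routes to the argmax."""
    x = _ensure(x)
    N, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    r = x.data.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    r = r.reshape(N, H // 2, W // 2, C, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, H // 2, W // 2, C, 4), dtype=DTYPE)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x._accum(gx.reshape(N, H, W, C))

    return Tensor._from_op(out, (x,), backward)
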