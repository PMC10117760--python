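"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in :mod:`neuroseg2.network` is a small two-stage
detector trained on CPU at modest problem sizes, so a compact define-by-run
tape suffices: every operation builds a node holding its inputs and a closure
that accumulates gradients into them.  Arrays are float32 throughout.

Only the operations the network needs are provided (elementwise arithmetic,
matmul, 2-D convolution, slicing/gather, pad, concat, reductions, the usual
activations).  Gradients for broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this node."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._prev:
                visit(p)
            topo.append(node)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return self._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -- activations / transcendental -----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float32)

        def backward(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        if isinstance(axis, tuple):
            out = self
            # reduce one axis at a time (descending so indices stay valid)
            for ax in sorted(axis, reverse=True):
                out = out.sum(axis=ax, keepdims=keepdims)
            return out * float(1.0 / n)
        return self.sum(axis=axis, keepdims=keepdims) * float(1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def backward(g):
            a._accumulate(g.reshape(a.data.shape))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, key, g)
            a._accumulate(ga)

        return self._make(a.data[key], (a,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the two trailing axes by ``pad`` on each side."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]

        def backward(g):
            sl = tuple([slice(None)] * (a.ndim - 2) + [slice(pad, -pad)] * 2)
            a._accumulate(g[sl])

        return self._make(np.pad(a.data, width), (a,), backward)

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis only."""
        if before == 0 and after == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 1) + [(before, after)]
        end = -after if after else None

        def backward(g):
            sl = tuple([slice(None)] * (a.ndim - 1) + [slice(before, end)])
            a._accumulate(g[sl])

        return self._make(np.pad(a.data, width), (a,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            t._accumulate(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xg = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    x = Tensor._coerce(x)
    n = x.data.shape[0]
    f, cin, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(f, -1)
    out_data = np.einsum("fk,nkl->nfl", wmat, cols).reshape(n, f, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)
    prev = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(n, f, ho * wo)
        if w.requires_grad:
            w._accumulate(np.einsum("nfl,nkl->fk", gf, cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.einsum("fk,nfl->nkl", wmat, gf)
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in prev)
    if out.requires_grad:
        out._prev = prev
        out._backward = backward
    return out
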