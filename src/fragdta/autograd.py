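"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape: just the operations the package's networks need
(dense algebra, ReLU/softplus, segment scatter/gather for message passing,
stride-1 "same" 2D convolution, max pooling).  Arrays are float32 throughout;
gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.

Convolution gradients are themselves expressed as correlations (transposed
convolution), so every heavy step is a BLAS matmul; the only scatter loops are
the per-row ``np.add.at`` calls used by graph aggregation, whose index arrays
are edge lists (small).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "gather_rows",
    "global_max_pool",
    "matmul",
    "maxpool2d",
    "relu",
    "scatter_sum",
    "softplus",
]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _DTYPE and np.issubdtype(a.dtype, np.floating):
        a = a.astype(_DTYPE)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
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

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)

    def square(self):
        return self * self

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._from_op(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).astype(_DTYPE))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g2, a.shape).astype(_DTYPE))

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- functional ops -----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor._from_op(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._from_op(x.data * mask, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) computed stably."""
    d = x.data
    e = np.exp(-np.abs(d))
    out = np.maximum(d, 0) + np.log1p(e)
    sig = np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(d.dtype)

    def backward(g):
        if x.requires_grad:
            x._accum(g * sig)

    return Tensor._from_op(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accum(gx)

    return Tensor._from_op(x.data[idx], (x,), backward)


def scatter_sum(x: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise segment sum: out[k] = sum of x rows i with idx[i] == k."""
    idx = np.asarray(idx, dtype=np.int64)
    out = np.zeros((num_segments,) + x.shape[1:], dtype=_DTYPE)
    np.add.at(out, idx, x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g[idx])

    return Tensor._from_op(out, (x,), backward)


def _corr2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Plain stride-1 'same' cross-correlation, (B,C,H,W) x (F,C,kh,kw)."""
    B, C, H, W = x.shape
    F, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * kh * kw)
    out = cols @ w.reshape(F, -1).T
    return out.reshape(B, H, W, F).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1, zero 'same'-padded 2D convolution (odd kernels only).

    x: (B, C, H, W); w: (F, C, kh, kw); b: (F,).  Output (B, F, H, W).
    """
    F, C, kh, kw = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    out, cols = _corr2d(x.data, w.data)
    out = out + b.data[None, :, None, None]
    B, _, H, W = x.shape

    def backward(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        g2 = g.transpose(0, 2, 3, 1).reshape(B * H * W, F)
        if w.requires_grad:
            dw = cols.T @ g2                      # (C*kh*kw, F)
            w._accum(dw.T.reshape(F, C, kh, kw))
        if x.requires_grad:
            # grad wrt input = correlation of g with spatially-flipped,
            # channel-swapped kernels (valid because stride 1, same padding,
            # odd kernels).
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _corr2d(g, np.ascontiguousarray(wflip))
            x._accum(dx)

    return Tensor._from_op(out, (x, w, b), backward)


def maxpool2d(x: Tensor, k: int | tuple[int, int] = 2) -> Tensor:
    """Non-overlapping max pooling with window ``k`` (int or (kh, kw));
    trailing rows/cols that do not fill a window are dropped."""
    kh, kw = (k, k) if isinstance(k, int) else k
    B, C, H, W = x.shape
    Ho, Wo = H // kh, W // kw
    if Ho == 0 or Wo == 0:
        raise ValueError(f"pooling window {k} larger than input {(H, W)}")
    xt = x.data[:, :, : Ho * kh, : Wo * kw]
    win = xt.reshape(B, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, kh * kw
    )
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros_like(win)
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : Ho * kh, : Wo * kw] = gw.reshape(
            B, C, Ho, Wo, kh, kw
        ).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * kh, Wo * kw)
        x._accum(gx)

    return Tensor._from_op(out, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C), max over the spatial grid."""
    B, C, H, W = x.shape
    flat = x.data.reshape(B, C, H * W)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        x._accum(gx.reshape(x.shape))

    return Tensor._from_op(out, (x,), backward)
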