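"""Reverse-mode automatic differentiation over NumPy arrays.

This is the package's compute backend: a small tape-based autodiff engine
providing exactly the operations the models need — broadcasting arithmetic,
batched matmul, softmax, 3D convolution (stride >= 1, zero padding), 2x2x2 max
pooling, nearest-neighbour upsampling, and a fused softmax cross-entropy.

Gradients are accumulated into ``Tensor.grad`` (NumPy arrays) by
``Tensor.backward()``, which walks the recorded graph in reverse topological
order.  A global switch (:func:`no_grad`) disables graph recording for
inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep conv graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # keep python scalars at float32 so they do not upcast the graph
            return Tensor(np.float32(other))
        return Tensor(np.asarray(other))

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data + b.data

        def backward(g):
            a._accum(g)
            b._accum(g)

        return Tensor._result(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data * b.data

        def backward(g):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return Tensor._result(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._result(out_data, (a,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def backward(g):
            a._accum(np.ascontiguousarray(g).reshape(orig))

        # contiguous output so downstream reductions are layout-independent
        out = np.ascontiguousarray(a.data.reshape(shape))
        return Tensor._result(out, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(a.data[idx], (a,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape) if ga.shape != a.data.shape else ga)
            b._accum(_unbroadcast(gb, b.data.shape) if gb.shape != b.data.shape else gb)

        return Tensor._result(out_data, (a, b), backward)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accum(y * (g - dot))

        return Tensor._result(y, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._result(out_data, ts, backward)


# ---------------------------------------------------------------------------
# Spatial operations (volumes laid out as (B, C, D, H, W))
# ---------------------------------------------------------------------------

def _conv3d_forward_raw(x: np.ndarray, w: np.ndarray, stride: int,
                        pad: tuple[int, int]) -> np.ndarray:
    """Cross-correlation of x (B,C,D,H,W) with w (O,C,k,k,k).

    Computed as one GEMM per kernel offset, which keeps peak memory at a few
    copies of the input rather than a full im2col buffer.
    """
    B, C, D, H, W = x.shape
    O, Cw, k, _, _ = w.shape
    if Cw != C:
        raise ValueError(f"conv3d: input has {C} channels but weights expect {Cw}")
    lo, hi = pad
    xp = np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi)))
    Do = (D + lo + hi - k) // stride + 1
    Ho = (H + lo + hi - k) // stride + 1
    Wo = (W + lo + hi - k) // stride + 1
    out2 = np.zeros((B * Do * Ho * Wo, O), dtype=x.dtype)
    for d0 in range(k):
        for d1 in range(k):
            for d2 in range(k):
                sl = xp[:, :,
                        d0:d0 + stride * Do:stride,
                        d1:d1 + stride * Ho:stride,
                        d2:d2 + stride * Wo:stride]
                x2 = np.ascontiguousarray(sl.transpose(0, 2, 3, 4, 1)).reshape(-1, C)
                out2 += x2 @ w[:, :, d0, d1, d2].T
    return out2.reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: str | int = "same") -> Tensor:
    """3D convolution (cross-correlation) with zero padding.

    ``padding='same'`` preserves the spatial extent at stride 1 (requires an
    odd kernel); an integer pads symmetrically by that amount.
    """
    k = w.data.shape[2]
    if padding == "same":
        if k % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel size")
        pad = (k // 2, k // 2)
    elif padding == "valid":
        pad = (0, 0)
    else:
        pad = (int(padding), int(padding))
    x_t, w_t = x, w
    out_data = _conv3d_forward_raw(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    B, C, D, H, W = x.data.shape
    O = w.data.shape[0]
    lo, hi = pad

    def backward(g):
        # g: (B, O, Do, Ho, Wo)
        Do, Ho, Wo = g.shape[2:]
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, O)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0).reshape(b.data.shape))
        need_x = x_t.requires_grad
        need_w = w_t.requires_grad
        if not (need_x or need_w):
            return
        xp = np.pad(x_t.data, ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi)))
        gw = np.zeros_like(w_t.data) if need_w else None
        gxp = np.zeros_like(xp) if need_x else None
        kk = w_t.data.shape[2]
        for d0 in range(kk):
            for d1 in range(kk):
                for d2 in range(kk):
                    idx = (slice(None), slice(None),
                           slice(d0, d0 + stride * Do, stride),
                           slice(d1, d1 + stride * Ho, stride),
                           slice(d2, d2 + stride * Wo, stride))
                    if need_w:
                        x2 = np.ascontiguousarray(
                            xp[idx].transpose(0, 2, 3, 4, 1)).reshape(-1, C)
                        gw[:, :, d0, d1, d2] += g2.T @ x2
                    if need_x:
                        contrib = g2 @ w_t.data[:, :, d0, d1, d2]  # (BP, C)
                        gxp[idx] += contrib.reshape(B, Do, Ho, Wo, C).transpose(
                            0, 4, 1, 2, 3)
        if need_w:
            w_t._accum(gw)
        if need_x:
            if hi > 0:
                core = gxp[:, :, lo:-hi or None, lo:-hi or None, lo:-hi or None]
            else:
                core = gxp[:, :, lo:, lo:, lo:]
            x_t._accum(core)

    parents = (x_t, w_t) if b is None else (x_t, w_t, b)
    return Tensor._result(out_data, parents, backward)


def max_pool3d(x: Tensor, window: int = 2) -> Tensor:
    """Max pooling with window == stride; spatial dims must be divisible."""
    B, C, D, H, W = x.data.shape
    w = window
    if D % w or H % w or W % w:
        raise ValueError(
            f"max_pool3d: spatial dims {(D, H, W)} not divisible by window {w}")
    blocks = x.data.reshape(B, C, D // w, w, H // w, w, W // w, w)
    blocks = np.ascontiguousarray(blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7))
    flat = blocks.reshape(B, C, D // w, H // w, W // w, w ** 3)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    a = x

    def backward(g):
        gflat = np.zeros((B, C, D // w, H // w, W // w, w ** 3), dtype=g.dtype)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gb = gflat.reshape(B, C, D // w, H // w, W // w, w, w, w)
        gb = gb.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        a._accum(gb)

    return Tensor._result(out_data, (a,), backward)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of (B, C, D, H, W) by an integer factor."""
    f = factor
    a = x
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    B, C, D, H, W = x.data.shape

    def backward(g):
        gb = g.reshape(B, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
        a._accum(gb)

    return Tensor._result(out_data, (a,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (fused softmax)."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(np.maximum(p[np.arange(n), labels], eps)).mean()
    a = logits

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        a._accum(g * grad / n)

    return Tensor._result(np.asarray(loss, dtype=p.dtype), (a,), backward)
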