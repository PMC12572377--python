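"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's networks are small (tiny convolutional backbones, a short
transformer encoder, a handful of MLP heads), so a compact tape-based engine
over ``numpy.ndarray`` is sufficient and keeps the whole stack dependency-free
and deterministic on CPU.  Every :class:`Tensor` records its parents and a
closure that scatters the incoming gradient; :meth:`Tensor.backward` runs a
topological sweep.  Gradients are accumulated on *every* tensor in the graph
(not just leaves), which is what lets Grad-CAM read gradients of intermediate
convolutional activations without extra machinery.

All arithmetic is float64: the masking/permutation invariances of the fusion
model are asserted at 1e-6, comfortably inside float64 round-off even for
re-ordered reductions.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / scoring)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._bwd = bwd if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar backward")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # -- operators -----------------------------------------------------------
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
        if isinstance(other, Tensor):
            return mul(self, other ** -1.0)
        return mul(self, 1.0 / other)

    def __pow__(self, p: float):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    # convenience reductions / shapes
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, bwd) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad])
    if req:
        t._bwd = bwd
    return t


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a = _as_tensor(a)
    if not isinstance(b, Tensor):
        bval = np.asarray(b, dtype=np.float64)

        def bwd_s(g):
            a._accum(_unbroadcast(g * bval, a.data.shape))

        return _make(a.data * bval, (a,), bwd_s)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        a._accum(_unbroadcast(g * p * np.power(a.data, p - 1), a.data.shape))

    return _make(np.power(a.data, p), (a,), bwd)


def texp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), bwd)


def tlog(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        a._accum(g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        a._accum(g * mask)

    return _make(a.data * mask, (a,), bwd)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    a = _as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data / _SQRT2))

    def bwd(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        a._accum(g * (cdf + a.data * pdf))

    return _make(a.data * cdf, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accum(g * s * (1.0 - s))

    return _make(s, (a,), bwd)


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    th = np.tanh(a.data)

    def bwd(g):
        a._accum(g * (1.0 - th * th))

    return _make(th, (a,), bwd)


# ---------------------------------------------------------------------------
# reductions, shaping, indexing
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy() if np.ndim(g) else np.full_like(a.data, g))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape))

    return _make(out_data, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tmax(a: Tensor, axis: int) -> Tensor:
    """Max over one axis; gradient flows to the (first) argmax entries."""
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    out_data = np.squeeze(out_data, axis=axis)

    def bwd(g):
        buf = np.zeros_like(a.data)
        np.put_along_axis(buf, np.expand_dims(idx, axis),
                          np.expand_dims(g, axis), axis=axis)
        a._accum(buf)

    return _make(out_data, (a,), bwd)


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.data.shape

    def bwd(g):
        a._accum(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes=None) -> Tensor:
    a = _as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bwd)


def take(a: Tensor, idx) -> Tensor:
    """Basic/advanced indexing with scatter-add backward."""
    a = _as_tensor(a)

    def bwd(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accum(buf)

    return _make(a.data[idx], (a,), bwd)


def scatter_rows(src: Tensor, row_idx: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of ``src`` at ``row_idx`` in a zero tensor of ``n_rows`` rows."""
    src = _as_tensor(src)
    out_data = np.zeros((n_rows,) + src.data.shape[1:], dtype=src.data.dtype)
    out_data[row_idx] = src.data

    def bwd(g):
        src._accum(g[row_idx])

    return _make(out_data, (src,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(out_data, tuple(ts), bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def bwd(g):
        gs = np.moveaxis(g, axis, 0)
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(gs[i])

    return _make(out_data, tuple(ts), bwd)


# ---------------------------------------------------------------------------
# linear algebra and fused NN primitives
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bwd)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    return _make(y, (a,), bwd)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    ls = x - lse

    def bwd(g):
        sm = np.exp(ls)
        a._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(ls, (a,), bwd)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalisation over the last axis, fused forward/backward."""
    a, gain, bias = _as_tensor(a), _as_tensor(gain), _as_tensor(bias)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data
    n = a.data.shape[-1]

    def bwd(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if a.requires_grad:
            gx = g * gain.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            a._accum(inv * (term1 - term2 - term3))

    return _make(out_data, (a, gain, bias), bwd)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    # (n, oh, ow, c*kh*kw)
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw)
    return np.ascontiguousarray(col), oh, ow


def _col2im(col: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=col.dtype)
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    col6 = col.reshape(n, oh, ow, c, kh, kw)
    for ki in range(kh):
        for kj in range(kw):
            out[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += (
                col6[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            )
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution via im2col.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin*kh*kw) with kernel geometry carried
    by the caller; here ``w`` is (Cout, Cin, kh, kw).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    cout, cin, kh, kw = w.data.shape
    col, oh, ow = _im2col(x.data, kh, kw, stride, pad)  # (N, oh, ow, cin*kh*kw)
    wmat = w.data.reshape(cout, -1)  # (cout, K)
    out_data = col @ wmat.T  # (N, oh, ow, cout)
    out_data = out_data.transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1)  # (N, oh, ow, cout)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.tensordot(gmat, col, axes=([0, 1, 2], [0, 1, 2]))  # (cout, K)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcol = gmat @ wmat  # (N, oh, ow, K)
            x._accum(_col2im(gcol, x.data.shape, kh, kw, stride, pad))

    return _make(out_data, parents, bwd)
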