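"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine records a tape of operations on :class:`Tensor` objects and
replays it backwards to accumulate gradients.  Only the operations needed
by the segmentation network are implemented: 2-D convolution, 2×2 max
pooling, global average/max pooling, bilinear resizing, batch
normalisation, elementwise arithmetic with broadcasting, sigmoid/ReLU,
log/power/clip, channel concatenation and full reductions.

Every backward rule is exercised by central finite-difference checks in
the test suite.  Arrays keep whatever float dtype they come in with
(float32 in the network, float64 in gradient checks).
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (used during inference)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An n-d array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._parents = ()
        self._backward_fn = None

    # -- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autograd -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward_fn is None:
                continue
            for parent, pg in zip(t._parents, t._backward_fn(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward_fn = backward_fn
    return out


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(data, (a, b), bwd)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bwd(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _make(data, (a, b), bwd)


def power(a, exponent):
    a = _as_tensor(a)
    data = a.data ** exponent

    def bwd(g):
        return (g * exponent * a.data ** (exponent - 1),)

    return _make(data, (a,), bwd)


def log(a):
    a = _as_tensor(a)
    data = np.log(a.data)

    def bwd(g):
        return (g / a.data,)

    return _make(data, (a,), bwd)


def clip(a, lo, hi):
    """Clamp; gradient is zero outside [lo, hi] (subgradient convention)."""
    a = _as_tensor(a)
    data = np.clip(a.data, lo, hi)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(a.data.dtype)

    def bwd(g):
        return (g * inside,)

    return _make(data, (a,), bwd)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0)

    def bwd(g):
        return (g * mask,)

    return _make(data, (a,), bwd)


def sigmoid(a):
    from scipy.special import expit

    a = _as_tensor(a)
    data = expit(a.data)

    def bwd(g):
        return (g * data * (1.0 - data),)

    return _make(data, (a,), bwd)


def tensor_sum(a):
    a = _as_tensor(a)
    data = a.data.sum()

    def bwd(g):
        return (np.broadcast_to(g, a.data.shape).astype(a.data.dtype),)

    return _make(data, (a,), bwd)


def mean(a):
    a = _as_tensor(a)
    n = a.data.size
    data = a.data.mean()

    def bwd(g):
        return (np.broadcast_to(g / n, a.data.shape).astype(a.data.dtype),)

    return _make(data, (a,), bwd)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tensors, bwd)


def reshape(a, shape):
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bwd(g):
        return (g.reshape(a.data.shape),)

    return _make(data, (a,), bwd)


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation, NCHW layout, via im2col + GEMM.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        parents.append(b)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    # shift-and-matmul decomposition: one GEMM per kernel offset keeps the
    # operands near-contiguous, which is far faster than im2col at high
    # spatial resolution
    out = np.zeros((cout, n, ho, wo), dtype=x.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
            out += np.tensordot(w.data[:, :, ki, kj], xs, axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        xp_b = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        # one contiguous (Cout, N*Ho*Wo) copy of g shared by all offsets
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp_b)
        for ki in range(kh):
            for kj in range(kw):
                xs = np.ascontiguousarray(
                    xp_b[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                    .transpose(1, 0, 2, 3)).reshape(cin, -1)
                gw[:, :, ki, kj] = g2 @ xs.T
                t = (w.data[:, :, ki, kj].T @ g2).reshape(cin, n, ho, wo)
                gxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    t.transpose(1, 0, 2, 3)
        gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return _make(out, parents, bwd)


def max_pool2(x):
    """2×2 max pooling, stride 2; odd trailing rows/cols are -inf padded."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ph, pw = h % 2, w % 2
    xd = x.data
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
    ho, wo = xd.shape[2] // 2, xd.shape[3] // 2
    r = xd.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = np.argmax(r, axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros((n, c, ho, wo, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(n, c, ho * 2, wo * 2)
        return (gx[:, :, :h, :w],)

    return _make(out, (x,), bwd)


def global_avg_pool(x):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        return (np.broadcast_to(g / (h * w), x.data.shape).astype(g.dtype),)

    return _make(out, (x,), bwd)


def global_max_pool(x):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, -1)
    idx = np.argmax(flat, axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def bwd(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g.reshape(n, c, 1), axis=-1)
        return (gf.reshape(x.data.shape),)

    return _make(out, (x,), bwd)


# ---------------------------------------------------------------------------
# bilinear resizing (separable; backward is the transposed map)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centres)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    rows = np.arange(n_out)
    np.add.at(a, (rows, i0), 1.0 - f)
    np.add.at(a, (rows, i1), f)
    return a


def resize_bilinear(x, out_h, out_w):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _resize_matrix(h, out_h).astype(x.data.dtype)
    aw = _resize_matrix(w, out_w).astype(x.data.dtype)
    t = np.tensordot(x.data, ah, axes=([2], [1]))      # (N,C,W,Ho)
    out = np.tensordot(t, aw, axes=([2], [1]))         # (N,C,Ho,Wo)
    out = np.ascontiguousarray(out)

    def bwd(g):
        t2 = np.tensordot(g, aw, axes=([3], [0]))      # (N,C,Ho,W)
        gx = np.tensordot(t2, ah, axes=([2], [0]))     # (N,C,W,H)
        return (np.ascontiguousarray(np.moveaxis(gx, 3, 2)),)

    return _make(out, (x,), bwd)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean, running_var, training,
                 momentum=0.1, eps=1e-5):
    """Per-channel batch norm over (N, H, W).

    `running_mean`/`running_var` are plain numpy arrays updated in place
    when `training` is true.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def bwd(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gs = gamma.data.reshape(1, -1, 1, 1)
        if training:
            nhw = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gy = g * gs
            gx = (inv.reshape(1, -1, 1, 1) / nhw) * (
                nhw * gy
                - gy.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        else:
            gx = g * gs * inv.reshape(1, -1, 1, 1)
        return gx.astype(g.dtype), ggamma, gbeta

    return _make(out, (x, gamma, beta), bwd)
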