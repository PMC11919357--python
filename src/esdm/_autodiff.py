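"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the segmentation-denoising network: a
small define-by-run graph of :class:`Tensor` nodes with exactly the
operations the model family needs (strided/depthwise correlation, transposed
convolution via dilation, layer normalisation, batched matmul, softmax,
GeLU, bilinear upsampling). Gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "Parameter", "no_grad", "is_grad_enabled",
    "add", "mul", "matmul", "reshape", "transpose", "concat",
    "gelu", "sigmoid", "softmax", "log", "mean", "sum_", "power",
    "layer_norm", "conv2d", "dilate2d", "pad2d", "upsample_bilinear2x",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / target computation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break closure<->tensor reference cycles so the graph is freed by
        # reference counting rather than waiting for the cyclic collector
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # parameters are leaves even under no_grad model construction
        self.requires_grad = True


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    nextra = g.ndim - len(shape)
    if nextra > 0:
        g = g.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents: Sequence[Tensor], backward: Callable | None) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req,
                 _prev=tuple(p for p in parents if p.requires_grad),
                 _backward=None)
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    # Python-scalar fast path preserves the array dtype (NEP 50)
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        out_data = a.data + b

        def _bwd_s():
            if a.requires_grad:
                a._accum(out.grad)

        out = _make(out_data, (a,), _bwd_s)
        return out
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def _bwd():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.shape))

    out = _make(out_data, (a, b), _bwd)
    return out


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        out_data = a.data * b

        def _bwd_s():
            if a.requires_grad:
                a._accum(out.grad * b)

        out = _make(out_data, (a,), _bwd_s)
        return out
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def _bwd():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.shape))

    out = _make(out_data, (a, b), _bwd)
    return out


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def _bwd():
        if a.requires_grad:
            a._accum(out.grad * p * a.data ** (p - 1.0))

    out = _make(out_data, (a,), _bwd)
    return out


def log(a, eps: float = 0.0) -> Tensor:
    a = _as_tensor(a)
    x = np.maximum(a.data, eps) if eps else a.data
    out_data = np.log(x)

    def _bwd():
        if a.requires_grad:
            a._accum(out.grad / x)

    out = _make(out_data, (a,), _bwd)
    return out


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def _bwd():
        if a.requires_grad:
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

    out = _make(out_data, (a,), _bwd)
    return out


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(a) -> Tensor:
    a = _as_tensor(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = x * phi

    def _bwd():
        if a.requires_grad:
            pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
            a._accum(out.grad * (phi + x * pdf))

    out = _make(out_data, (a,), _bwd)
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def _bwd():
        if a.requires_grad:
            a._accum(out.grad * s * (1.0 - s))

    out = _make(s, (a,), _bwd)
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def _bwd():
        if a.requires_grad:
            g = out.grad
            a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out = _make(y, (a,), _bwd)
    return out


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def _bwd():
        if a.requires_grad:
            a._accum(out.grad.reshape(a.shape))

    out = _make(out_data, (a,), _bwd)
    return out


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def _bwd():
        if a.requires_grad:
            a._accum(np.transpose(out.grad, inv))

    out = _make(out_data, (a,), _bwd)
    return out


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def _bwd():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(ts, parts):
            if t.requires_grad:
                t._accum(g)

    out = _make(out_data, tuple(ts), _bwd)
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def _bwd():
        g = out.grad
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    out = _make(out_data, (a, b), _bwd)
    return out


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def _bwd():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if a.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            a._accum(inv * (gx - m1 - xhat * m2))

    out = _make(out_data, (a, gamma, beta), _bwd)
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _corr_forward(x, w, stride, pad, groups):
    """Correlation as kh*kw shifted GEMMs in NHWC layout.

    Returns (output NCHW, saved slices); the saved NHWC input slices are
    reused for the weight gradient.
    """
    n, cin, _, _ = x.shape
    cout, cin_g, kh, kw = w.shape
    if groups != 1 and not (groups == cin and cout == cin and cin_g == 1):
        # pragma: no cover - model only uses dense or depthwise
        raise NotImplementedError("groups must be 1 or C (depthwise)")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))      # NHWC
    hp, wp = xt.shape[1], xt.shape[2]
    ho, wo = (hp - kh) // stride + 1, (wp - kw) // stride + 1
    if groups == 1:
        cols = np.empty((n, ho, wo, kh * kw, cin), dtype=x.dtype)
        for k in range(kh):
            for l in range(kw):
                cols[:, :, :, k * kw + l, :] = \
                    xt[:, k:k + (ho - 1) * stride + 1:stride,
                       l:l + (wo - 1) * stride + 1:stride, :]
        colm = cols.reshape(n * ho * wo, kh * kw * cin)
        wmat = w.transpose(2, 3, 1, 0).reshape(kh * kw * cin, cout)
        out = (colm @ wmat).reshape(n, ho, wo, cout)
        saved = colm
    else:
        out = np.zeros((n, ho, wo, cout), dtype=x.dtype)
        saved = []
        for k in range(kh):
            for l in range(kw):
                v = xt[:, k:k + (ho - 1) * stride + 1:stride,
                       l:l + (wo - 1) * stride + 1:stride, :]
                out += v * w[:, 0, k, l][None, None, None, :]
                saved.append(v)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), saved


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout; groups in {1, C} (depthwise)."""
    x, w = _as_tensor(x), _as_tensor(w)
    out_data, saved = _corr_forward(x.data, w.data, stride, pad, groups)
    kh, kw = w.shape[2], w.shape[3]

    def _bwd():
        g = out.grad
        if w.requires_grad:
            gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))   # NHWC
            if groups == 1:
                cout, cin = w.shape[0], w.shape[1]
                gm = gt.reshape(-1, cout)
                gw = (saved.T @ gm).reshape(kh, kw, cin, cout)
                gw = np.ascontiguousarray(gw.transpose(3, 2, 0, 1))
            else:
                gw = np.empty_like(w.data)
                for k in range(kh):
                    for l in range(kw):
                        v = saved[k * kw + l]
                        gw[:, 0, k, l] = (v * gt).sum(axis=(0, 1, 2))
            w._accum(gw)
        if x.requires_grad:
            # transposed correlation: dilate g by stride, pad by k-1-pad,
            # correlate with spatially flipped, channel-swapped kernel
            n, _, ho, wo = g.shape
            hin, win = x.shape[2], x.shape[3]
            gd = np.zeros((n, g.shape[1],
                           (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                          dtype=g.dtype)
            gd[:, :, ::stride, ::stride] = g
            ph, pw = kh - 1 - pad, kw - 1 - pad
            # guard: needed input extent may exceed dilated grad extent
            eh = hin + 2 * pad - kh - (gd.shape[2] - 1)
            ew = win + 2 * pad - kw - (gd.shape[3] - 1)
            gd = np.pad(gd, ((0, 0), (0, 0),
                             (ph, ph + max(eh, 0)), (pw, pw + max(ew, 0))))
            wf = w.data[:, :, ::-1, ::-1]
            if groups == 1:
                wt = wf.transpose(1, 0, 2, 3)  # (Cin, Cout, kh, kw)
                gx, _ = _corr_forward(gd, wt, 1, 0, 1)
            else:
                gx, _ = _corr_forward(gd, wf, 1, 0, groups)
            x._accum(gx[:, :, :hin, :win])

    out = _make(out_data, (x, w), _bwd)
    if b is not None:
        out = add(out, reshape(b, (1, -1, 1, 1)))
    return out


def dilate2d(x, stride: int, extra: int = 0) -> Tensor:
    """Insert ``stride-1`` zeros between pixels (+``extra`` trailing zeros)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    out_data = np.zeros((n, c, (h - 1) * stride + 1 + extra,
                         (w - 1) * stride + 1 + extra), dtype=x.data.dtype)
    out_data[:, :, ::stride, ::stride][:, :, :h, :w] = x.data

    def _bwd():
        if x.requires_grad:
            x._accum(out.grad[:, :, ::stride, ::stride][:, :, :h, :w])

    out = _make(out_data, (x,), _bwd)
    return out


def pad2d(x, pad: int) -> Tensor:
    x = _as_tensor(x)
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    def _bwd():
        if x.requires_grad:
            x._accum(out.grad[:, :, pad:-pad, pad:-pad])

    out = _make(out_data, (x,), _bwd)
    return out


def _bilinear_indices(n_out: int, n_in: int):
    # src = j/2 convention: even outputs coincide with input samples. This
    # matches the grid of stride-2 convolutions (which sample at even pixel
    # coordinates), so skip features fused after upsampling stay registered
    # with encoder features across scales.
    src = np.arange(n_out) * (n_in / n_out)
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, (1.0 - frac), frac


def upsample_bilinear2x(x) -> Tensor:
    """Bilinear upsampling by a factor of 2 (align_corners=False)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    r0, r1, wr0, wr1 = _bilinear_indices(2 * h, h)
    c0, c1, wc0, wc1 = _bilinear_indices(2 * w, w)
    wr0, wr1, wc0, wc1 = (a.astype(x.data.dtype)
                          for a in (wr0, wr1, wc0, wc1))
    xh = (x.data[:, :, r0, :] * wr0[None, None, :, None]
          + x.data[:, :, r1, :] * wr1[None, None, :, None])
    out_data = (xh[:, :, :, c0] * wc0[None, None, None, :]
                + xh[:, :, :, c1] * wc1[None, None, None, :])

    def _bwd():
        if x.requires_grad:
            g = out.grad
            gh = np.zeros_like(xh)
            np.add.at(gh, (slice(None), slice(None), slice(None), c0),
                      g * wc0[None, None, None, :])
            np.add.at(gh, (slice(None), slice(None), slice(None), c1),
                      g * wc1[None, None, None, :])
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), r0, slice(None)),
                      gh * wr0[None, None, :, None])
            np.add.at(gx, (slice(None), slice(None), r1, slice(None)),
                      gh * wr1[None, None, :, None])
            x._accum(gx)

    out = _make(out_data, (x,), _bwd)
    return out
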