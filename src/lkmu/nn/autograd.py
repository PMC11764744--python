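"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the segmentation network needs:
stride-1 "same" convolutions (grouped, dilated, depthwise), batch
normalization, 2x2 max pooling, 2x bilinear upsampling, the
parameter-free spatial shift, elementwise arithmetic and the pointwise
nonlinearities used by the losses.  Convolutions are evaluated as a sum
over kernel taps of a pointwise (1x1) product applied to a shifted
frame, so the heavy lifting is BLAS matrix multiplication and no im2col
buffer is materialised.

All tensors are float32 NCHW unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "scale",
    "add_scalar",
    "relu",
    "sigmoid",
    "softplus",
    "square",
    "reduce_sum",
    "reduce_mean",
    "concat",
    "narrow",
    "conv2d",
    "batch_norm2d",
    "max_pool2x2",
    "upsample_bilinear2x",
    "spatial_shift",
    "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self):
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        if isinstance(other, Tensor):
            return add(self, other)
        return add_scalar(self, float(other))

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        return scale(self, float(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return sub(self, other)
        return add_scalar(self, -float(other))

    def __rsub__(self, other):
        return add_scalar(neg(self), float(other))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return div(self, other)
        return scale(self, 1.0 / float(other))

    def __neg__(self):
        return neg(self)

    # -- autodiff ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order topological sort (parents before children);
        # deliberately closure-free so no self-referential cycle keeps the
        # graph alive until the cyclic garbage collector runs
        order = []
        seen = set()
        stack = [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if expanded:
                order.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg
        # release references so intermediate buffers can be collected
        for t in order:
            t._backward = None
            t._parents = ()


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _result(data, parents, backward):
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = False
    out._parents = tuple(parents)
    out._backward = backward
    return out


def _needs_graph(*parents):
    return _GRAD_ENABLED and any(
        p.requires_grad or p._parents for p in parents
    )


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    data = a.data + b.data
    if not _needs_graph(a, b):
        return Tensor(data)
    return _result(data, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a, b):
    data = a.data - b.data
    if not _needs_graph(a, b):
        return Tensor(data)
    return _result(data, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a, b):
    data = a.data * b.data
    if not _needs_graph(a, b):
        return Tensor(data)
    return _result(data, (a, b), lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def div(a, b):
    data = a.data / b.data
    if not _needs_graph(a, b):
        return Tensor(data)
    return _result(data, (a, b), lambda g: (
        _unbroadcast(g / b.data, a.data.shape),
        _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)))


def neg(a):
    if not _needs_graph(a):
        return Tensor(-a.data)
    return _result(-a.data, (a,), lambda g: (-g,))


def scale(a, s):
    s = np.float32(s)
    if not _needs_graph(a):
        return Tensor(a.data * s)
    return _result(a.data * s, (a,), lambda g: (g * s,))


def add_scalar(a, s):
    s = np.float32(s)
    if not _needs_graph(a):
        return Tensor(a.data + s)
    return _result(a.data + s, (a,), lambda g: (g,))


def square(a):
    return mul(a, a)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a):
    data = np.maximum(a.data, 0.0)
    if not _needs_graph(a):
        return Tensor(data)
    mask = a.data > 0
    return _result(data, (a,), lambda g: (np.where(mask, g, 0.0),))


def sigmoid(a):
    from scipy.special import expit

    data = expit(a.data).astype(np.float32)
    if not _needs_graph(a):
        return Tensor(data)
    return _result(data, (a,), lambda g: (g * data * (1.0 - data),))


def softplus(a):
    """log(1 + exp(x)), evaluated stably."""
    from scipy.special import expit

    data = np.logaddexp(0.0, a.data.astype(np.float64)).astype(np.float32)
    if not _needs_graph(a):
        return Tensor(data)
    sig = expit(a.data).astype(np.float32)
    return _result(data, (a,), lambda g: (g * sig,))


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False):
    data = a.data.sum(axis=axis, keepdims=keepdims)
    data = np.asarray(data, dtype=np.float32)
    if not _needs_graph(a):
        return Tensor(data)

    def backward(g):
        g = np.asarray(g, dtype=np.float32)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_pos(axes, a.data.ndim)):
                g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _result(data, (a,), backward)


def a_pos(axes, ndim):
    return tuple(ax % ndim for ax in axes)


def reduce_mean(a, axis=None, keepdims=False):
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return scale(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concat(tensors, axis=1):
    data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _needs_graph(*tensors):
        return Tensor(data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return _result(data, tuple(tensors), backward)


def narrow(a, axis, start, length):
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = np.ascontiguousarray(a.data[idx])
    if not _needs_graph(a):
        return Tensor(data)

    def backward(g):
        out = np.zeros_like(a.data)
        out[idx] = g
        return (out,)

    return _result(data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _tap_slices(ey, ex, H, W):
    """Destination / source spatial slices realising y[i] += z[i + e],
    or None when the displacement exceeds the frame (no overlap)."""
    if abs(ey) >= H or abs(ex) >= W:
        return None, None
    dst = (slice(max(0, -ey), H - max(0, ey)), slice(max(0, -ex), W - max(0, ex)))
    src = (slice(max(0, ey), H - max(0, -ey)), slice(max(0, ex), W - max(0, -ex)))
    return dst, src


def _conv2d_forward(x, w, bias, dilation, groups):
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    ch = (kh - 1) // 2
    cw = (kw - 1) // 2
    if groups == C and Cg == 1 and O == C:
        # depthwise: per-channel scale-and-shift accumulation
        y = np.zeros((B, C, H, W), dtype=np.float32)
        for ti in range(kh):
            for tj in range(kw):
                ey, ex = (ti - ch) * dilation, (tj - cw) * dilation
                dst, src = _tap_slices(ey, ex, H, W)
                if dst is None:
                    continue
                wt = w[:, 0, ti, tj][None, :, None, None]
                y[:, :, dst[0], dst[1]] += x[:, :, src[0], src[1]] * wt
    else:
        xt = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(C, B * H * W)
        acc = np.zeros((O, B, H, W), dtype=np.float32)
        og = O // groups
        for g in range(groups):
            xg = xt[g * Cg:(g + 1) * Cg]
            accg = acc[g * og:(g + 1) * og]
            for ti in range(kh):
                for tj in range(kw):
                    ey, ex = (ti - ch) * dilation, (tj - cw) * dilation
                    dst, src = _tap_slices(ey, ex, H, W)
                    if dst is None:
                        continue
                    z = (w[g * og:(g + 1) * og, :, ti, tj] @ xg)
                    z = z.reshape(og, B, H, W)
                    if ey == 0 and ex == 0:
                        accg += z
                    else:
                        accg[:, :, dst[0], dst[1]] += z[:, :, src[0], src[1]]
        y = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
    if bias is not None:
        y += bias[None, :, None, None]
    return y


def _conv2d_backward(g, x, w, dilation, groups, need_x, need_bias):
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    ch = (kh - 1) // 2
    cw = (kw - 1) // 2
    gw = np.zeros_like(w)
    gb = g.sum(axis=(0, 2, 3)) if need_bias else None
    gx = None
    depthwise = groups == C and Cg == 1 and O == C
    if depthwise:
        gx = np.zeros_like(x) if need_x else None
        for ti in range(kh):
            for tj in range(kw):
                ey, ex = (ti - ch) * dilation, (tj - cw) * dilation
                dst, src = _tap_slices(ey, ex, H, W)
                if dst is None:
                    continue
                gslice = g[:, :, dst[0], dst[1]]
                xslice = x[:, :, src[0], src[1]]
                gw[:, 0, ti, tj] = np.einsum("bchw,bchw->c", gslice, xslice)
                if need_x:
                    gx[:, :, src[0], src[1]] += gslice * w[:, 0, ti, tj][None, :, None, None]
        return gx, gw, gb

    og = O // groups
    gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3))  # (O, B, H, W)
    gacc = np.zeros((C, B, H, W), dtype=np.float32) if need_x else None
    for grp in range(groups):
        gg = gt[grp * og:(grp + 1) * og]
        ggf = gg.reshape(og, B * H * W)
        for ti in range(kh):
            for tj in range(kw):
                ey, ex = (ti - ch) * dilation, (tj - cw) * dilation
                dst, src = _tap_slices(ey, ex, H, W)
                if dst is None:
                    continue
                # weight gradient: correlate grad with the input frame
                gw[grp * og:(grp + 1) * og, :, ti, tj] = np.tensordot(
                    g[:, grp * og:(grp + 1) * og, dst[0], dst[1]],
                    x[:, grp * Cg:(grp + 1) * Cg, src[0], src[1]],
                    axes=([0, 2, 3], [0, 2, 3]),
                )
                if need_x:
                    z = (w[grp * og:(grp + 1) * og, :, ti, tj].T @ ggf)
                    z = z.reshape(Cg, B, H, W)
                    # transpose relation: gx[i + e] += w^T g[i]
                    gacc[grp * Cg:(grp + 1) * Cg][:, :, src[0], src[1]] += \
                        z[:, :, dst[0], dst[1]]
    if need_x:
        gx = np.ascontiguousarray(gacc.transpose(1, 0, 2, 3))
    return gx, gw, gb


def conv2d(x, weight, bias=None, dilation=1, groups=1):
    """Stride-1 zero-padded "same" 2-D convolution (cross-correlation).

    ``weight`` has shape (out_channels, in_channels // groups, kh, kw) with
    odd kernel sides; padding is implicit: ``dilation * (k - 1) // 2``.
    """
    O, Cg, kh, kw = weight.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sides for same padding")
    if x.data.shape[1] != Cg * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]} channels, "
            f"weight expects {Cg * groups}")
    bias_arr = bias.data if bias is not None else None
    data = _conv2d_forward(x.data, weight.data, bias_arr, dilation, groups)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _needs_graph(*parents):
        return Tensor(data)

    def backward(g):
        need_x = x.requires_grad or bool(x._parents)
        gx, gw, gb = _conv2d_backward(
            g, x.data, weight.data, dilation, groups, need_x, bias is not None)
        if bias is None:
            return (gx, gw)
        return (gx, gw, gb)

    return _result(data, parents, backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean, running_var,
                 training, momentum=0.1, eps=1e-5):
    """Channelwise batch normalization with affine transform.

    ``running_mean`` / ``running_var`` are plain numpy buffers updated in
    place during training (unbiased variance, torch convention).
    """
    xd = x.data
    B, C, H, W = xd.shape
    n = B * H * W
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        if n > 1:
            unbiased = var * (n / (n - 1))
        else:
            unbiased = var
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * ivar[None, :, None, None]
    data = (gamma.data[None, :, None, None] * xhat
            + beta.data[None, :, None, None]).astype(np.float32)
    parents = (x, gamma, beta)
    if not _needs_graph(*parents):
        return Tensor(data)
    xhat = xhat.astype(np.float32)

    def backward(g):
        ggamma = np.einsum("bchw,bchw->c", g, xhat)
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            # closed-form batch-norm input gradient
            s1 = gxhat.sum(axis=(0, 2, 3))
            s2 = np.einsum("bchw,bchw->c", gxhat, xhat)
            gx = (gxhat
                  - (s1 / n)[None, :, None, None]
                  - xhat * (s2 / n)[None, :, None, None])
            gx *= ivar[None, :, None, None]
        else:
            gx = gxhat * ivar[None, :, None, None]
        return (gx.astype(np.float32), ggamma, gbeta)

    return _result(data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resizing / shifting
# ---------------------------------------------------------------------------

def max_pool2x2(x):
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    windows = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = windows.argmax(axis=-1)
    data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    if not _needs_graph(x):
        return Tensor(data)

    def backward(g):
        gwin = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(B, C, H, W).copy(),)

    return _result(data, (x,), backward)


_INTERP_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n):
    """(2n, n) interpolation matrix for x2 bilinear upsampling
    (half-pixel centres, i.e. align_corners=False)."""
    M = _INTERP_CACHE.get(n)
    if M is not None:
        return M
    M = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        s = (o + 0.5) / 2.0 - 0.5
        s0 = int(np.floor(s))
        t = s - s0
        i0 = min(max(s0, 0), n - 1)
        i1 = min(max(s0 + 1, 0), n - 1)
        M[o, i0] += 1.0 - t
        M[o, i1] += t
    _INTERP_CACHE[n] = M
    return M


def upsample_bilinear2x(x):
    B, C, H, W = x.data.shape
    Mh = _bilinear_matrix(H)
    Mw = _bilinear_matrix(W)
    data = Mh @ x.data @ Mw.T  # broadcast matmul over (B, C)
    if not _needs_graph(x):
        return Tensor(data)

    def backward(g):
        return ((Mh.T @ g @ Mw).astype(np.float32),)

    return _result(data.astype(np.float32), (x,), backward)


# eight max-norm-1 displacements, fixed order; channel group g moves by
# SHIFT_DISPLACEMENTS[g] (rows, cols), vacated positions are zero-filled
SHIFT_DISPLACEMENTS = (
    (-1, 0), (1, 0), (0, -1), (0, 1),
    (-1, -1), (-1, 1), (1, -1), (1, 1),
)


def _shift_forward(xd, displacements):
    B, C, H, W = xd.shape
    n = len(displacements)
    q = C // n
    y = np.zeros_like(xd)
    for g, (dy, dx) in enumerate(displacements):
        cs = slice(g * q, (g + 1) * q)
        # content moves by (dy, dx): y[i, j] = x[i - dy, j - dx]
        dst, src = _tap_slices(-dy, -dx, H, W)
        y[:, cs, dst[0], dst[1]] = xd[:, cs, src[0], src[1]]
    if C % n:
        y[:, n * q:] = xd[:, n * q:]
    return y


def spatial_shift(x, displacements=SHIFT_DISPLACEMENTS):
    """Group-wise spatial shift with zero fill (parameter-free, linear).

    Channels are split into ``len(displacements)`` contiguous equal groups;
    group ``g`` is translated by ``displacements[g]`` (rows, cols).  Any
    remainder channels are passed through unshifted.
    """
    data = _shift_forward(x.data, displacements)
    if not _needs_graph(x):
        return Tensor(data)

    def backward(g):
        inv = tuple((-dy, -dx) for dy, dx in displacements)
        return (_shift_forward(g, inv),)

    return _result(data, (x,), backward)
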