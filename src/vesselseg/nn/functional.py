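"""Differentiable operations for the numpy autodiff engine.

Array layout is NCHW throughout.  All convolutions are stride-1 with
'same' zero padding (odd kernels); upsampling by transposed convolution
is specialised to the 2x2-kernel / stride-2 case, which is the only one
a U-Net decoder needs and which reduces to an einsum plus interleaving.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor, make_op

# ---------------------------------------------------------------------------
# broadcasting-aware elementwise ops


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(grad, b.shape))

    return make_op(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(-grad, b.shape))

    return make_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(grad * a.data, b.shape))

    return make_op(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a.accumulate_grad(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b.accumulate_grad(_unbroadcast(gb, b.shape))

    return make_op(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# shape surgery


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    in_shape = x.shape
    out_data = x.data.reshape(shape)

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad.reshape(in_shape))

    return make_op(out_data, (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    x = as_tensor(x)
    inv = np.argsort(axes)
    out_data = x.data.transpose(axes)

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad.transpose(inv))

    return make_op(out_data, (x,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        pieces = np.split(grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate_grad(g)

    return make_op(out_data, tuple(tensors), backward)


def pad_edge2d(x: Tensor, ph: int, pw: int) -> Tensor:
    """Replicate-pad the two trailing spatial axes on the bottom/right."""
    x = as_tensor(x)
    out_data = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
    H, W = x.shape[-2:]

    def backward(grad):
        if not x.requires_grad:
            return
        g = grad.copy()
        if ph:
            g[..., H - 1, :] += g[..., H:, :].sum(axis=-2)
        g = g[..., :H, :]
        if pw:
            g[..., :, W - 1] += g[..., :, W:].sum(axis=-1)
        x.accumulate_grad(g[..., :, :W])

    return make_op(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities and reductions


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad * mask)

    return make_op(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad * out_data * (1.0 - out_data))

    return make_op(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad * (1.0 - out_data * out_data))

    return make_op(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    out_data = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(out_data, out=out_data)
    out_data /= out_data.sum(axis=axis, keepdims=True)

    def backward(grad):
        if x.requires_grad:
            dot = (grad * out_data).sum(axis=axis, keepdims=True)
            x.accumulate_grad(out_data * (grad - dot))

    return make_op(out_data, (x,), backward)


def mean(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.asarray(x.data.mean())
    n = x.size

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(grad / n, x.shape).astype(x.dtype))

    return make_op(out_data, (x,), backward)


def binary_cross_entropy(pred: Tensor, target, eps: float = 1e-7) -> Tensor:
    """Mean BCE  -[t log p + (1-t) log(1-p)] with probability clamping."""
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=pred.dtype)
    p = np.clip(pred.data, eps, 1.0 - eps)
    out_data = np.asarray(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean())
    n = p.size

    def backward(grad):
        if pred.requires_grad:
            g = (p - t) / (p * (1.0 - p)) / n
            pred.accumulate_grad(grad * g)

    return make_op(out_data, (pred,), backward)


# ---------------------------------------------------------------------------
# convolution


def _dilated_windows(xp: np.ndarray, kh: int, kw: int, d: int) -> np.ndarray:
    """(N,C,H',W',kh,kw) windows of the padded input, taps spaced by d."""
    eh, ew = (kh - 1) * d + 1, (kw - 1) * d + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))
    if d > 1:
        win = win[..., ::d, ::d]
    return win


def conv2d(x: Tensor, w: Tensor, b=None, dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 'same' cross-correlation.

    ``w`` has shape (C_out, C_in/groups, kh, kw); odd kernel extents only.
    """
    x, w = as_tensor(x), as_tensor(w)
    cout, cing, kh, kw = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel extents only")
    d = dilation
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    N, cin, H, W = x.shape
    if cin != cing * groups:
        raise ValueError("channel/groups mismatch")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _dilated_windows(xp, kh, kw, d)  # (N,cin,H,W,kh,kw)
    wing = win.reshape(N, groups, cing, H, W, kh, kw)
    wg = w.data.reshape(groups, cout // groups, cing, kh, kw)
    out = np.einsum("ngihwkl,goikl->ngohw", wing, wg, optimize=True)
    out = out.reshape(N, cout, H, W)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gg = grad.reshape(N, groups, cout // groups, H, W)
        if b is not None and b.requires_grad:
            b.accumulate_grad(grad.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("ngihwkl,ngohw->goikl", wing, gg, optimize=True)
            w.accumulate_grad(gw.reshape(w.shape))
        if x.requires_grad:
            gp = np.pad(grad, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gwin = _dilated_windows(gp, kh, kw, d)  # (N,cout,H,W,kh,kw)
            gwing = gwin.reshape(N, groups, cout // groups, H, W, kh, kw)
            wflip = wg[..., ::-1, ::-1]
            gx = np.einsum("ngohwkl,goikl->ngihw", gwing, wflip, optimize=True)
            x.accumulate_grad(gx.reshape(N, cin, H, W))

    return make_op(out, parents, backward)


def up_conv2x2(x: Tensor, w: Tensor, b=None) -> Tensor:
    """Transposed convolution, kernel 2x2, stride 2 (doubles H and W).

    ``w`` has shape (C_in, C_out, 2, 2).  Because kernel == stride the
    output blocks do not overlap: out[:, o, 2i+k, 2j+l] = sum_i x*w.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, cin, H, W = x.shape
    cin2, cout = w.shape[:2]
    if cin2 != cin:
        raise ValueError("channel mismatch")
    blk = np.einsum("nihw,iokl->nohkwl", x.data, w.data, optimize=True)
    out = blk.reshape(N, cout, 2 * H, 2 * W)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gblk = grad.reshape(N, cout, H, 2, W, 2)
        if b is not None and b.requires_grad:
            b.accumulate_grad(grad.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nihw,nohkwl->iokl", x.data, gblk, optimize=True)
            w.accumulate_grad(gw)
        if x.requires_grad:
            gx = np.einsum("nohkwl,iokl->nihw", gblk, w.data, optimize=True)
            x.accumulate_grad(gx)

    return make_op(out, parents, backward)


# ---------------------------------------------------------------------------
# pooling and resizing


def max_pool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 needs even spatial dims")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = r.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], grad[..., None], axis=-1)
        g = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate_grad(g.reshape(N, C, H, W))

    return make_op(out, (x,), backward)


def _avg_pool_even(x: Tensor, f: int) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = x.data.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))

    def backward(grad):
        if x.requires_grad:
            g = np.repeat(np.repeat(grad, f, axis=2), f, axis=3) / (f * f)
            x.accumulate_grad(g)

    return make_op(out, (x,), backward)


def avg_pool(x: Tensor, f: int) -> Tensor:
    """f x f average pooling; odd trailing rows/cols are replicate-padded."""
    x = as_tensor(x)
    H, W = x.shape[-2:]
    ph, pw = (-H) % f, (-W) % f
    if ph or pw:
        x = pad_edge2d(x, ph, pw)
    return _avg_pool_even(x, f)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centres)."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    A[np.arange(n_out), lo] += 1.0 - t
    A[np.arange(n_out), hi] += t
    return A


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    x = as_tensor(x)
    H, W = x.shape[-2:]
    Ho, Wo = out_hw
    Ah = _interp_matrix(Ho, H, x.dtype)
    Aw = _interp_matrix(Wo, W, x.dtype)
    out = np.einsum("oh,nchw,pw->ncop", Ah, x.data, Aw, optimize=True)

    def backward(grad):
        if x.requires_grad:
            gx = np.einsum("oh,ncop,pw->nchw", Ah, grad, Aw, optimize=True)
            x.accumulate_grad(gx)

    return make_op(out, (x,), backward)


# ---------------------------------------------------------------------------
# normalisation / regularisation


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W)."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    C = x.shape[1]
    shape = (1, C, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(grad):
        if gamma.requires_grad:
            gamma.accumulate_grad((grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate_grad(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(shape) * inv.reshape(shape)
            if training:
                n = x.data.size // C
                gxhat = grad * gamma.data.reshape(shape)
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / n - xhat * s2 / n) * inv.reshape(shape)
                x.accumulate_grad(gx)
            else:
                x.accumulate_grad(grad * gs)

    return make_op(out, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    x = as_tensor(x)
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    out = x.data * mask

    def backward(grad):
        if x.requires_grad:
            x.accumulate_grad(grad * mask)

    return make_op(out, (x,), backward)
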