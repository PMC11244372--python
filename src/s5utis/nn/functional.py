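"""Differentiable network primitives: convolutions, normalization, losses.

All spatial tensors are channel-first ``(B, C, H, W)``.  Convolutions use an
im2col/einsum lowering, which is the right trade-off for the small feature
maps this model runs on.  The FFT global convolution implements a causal
(top-left anchored) linear convolution whose kernel extent equals the
feature-map extent.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

from .tensor import Tensor, as_tensor, erf, make_op, mul, add

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "zero_stuff",
    "flip_spatial",
    "batch_norm2d",
    "gelu",
    "softmax",
    "softmax_cross_entropy",
    "fft_causal_conv2d",
    "bilinear_upsample2x",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _zero_pad(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if not (ph or pw):
        return x
    B, C, H, W = x.shape
    out = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=x.dtype)
    out[:, :, ph : ph + H, pw : pw + W] = x
    return out


def _conv1x1(x: Tensor, w: Tensor, b) -> Tensor:
    """Pointwise convolution as a batched channel GEMM."""
    B, C, H, W = x.shape
    Co = w.shape[0]
    x3 = x.data.reshape(B, C, H * W)
    w2 = w.data.reshape(Co, C)
    y = np.matmul(w2[None], x3).reshape(B, Co, H, W)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y += b.data.reshape(1, Co, 1, 1)
        parents.append(b)

    def backward(gy):
        gy3 = gy.reshape(B, Co, H * W)
        gw = np.matmul(gy3, x3.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gx = np.matmul(w2.T[None], gy3).reshape(x.shape)
        grads = [gx, gw]
        if b is not None:
            grads.append(gy.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return make_op(y, parents, backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, Ho: int, Wo: int) -> np.ndarray:
    B, C = xp.shape[:2]
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw]
    return cols


def conv2d(x, w, b=None, stride=1, padding=0, groups: int = 1) -> Tensor:
    """2D cross-correlation (conv in the deep-learning sense) with groups.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin/groups, kh, kw); ``b``: (Cout,).
    Pure depthwise convolutions (groups == Cin == Cout) take a tap-accumulation
    fast path; dense/grouped ones go through im2col + batched matmul.
    """
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    if C != Cg * groups or Co % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {w.shape}, groups {groups}"
        )
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d output would be empty for input {x.shape}, kernel {(kh, kw)}")

    if kh == kw == 1 and sh == sw == 1 and not (ph or pw) and groups == 1:
        return _conv1x1(x, w, b)
    if groups == 1:
        return _conv_dense(x, w, b, (sh, sw), (ph, pw), (Ho, Wo))

    xp = _zero_pad(x.data, ph, pw)
    depthwise = groups == C and Co == C and Cg == 1
    if not (depthwise and sh == sw == 1):
        return _conv_grouped(x, xp, w, b, (sh, sw), (ph, pw), groups, (Ho, Wo))

    # stride-1 depthwise: windowed einsum, one pass per direction
    wk = w.data.reshape(C, kh, kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    y = _dw_einsum("bchwij,cij->bchw", win, wk)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y = y + b.data.reshape(1, Co, 1, 1)
        parents.append(b)

    def backward(gy):
        gw = _dw_einsum("bchwij,bchw->cij", win, gy).reshape(w.shape)
        gyp = _zero_pad(gy, kh - 1 - ph, kw - 1 - pw)
        gwin = np.lib.stride_tricks.sliding_window_view(gyp, (kh, kw), axis=(2, 3))
        gx = _dw_einsum("bchwij,cij->bchw", gwin, wk[:, ::-1, ::-1])
        grads = [gx.astype(x.dtype), gw]
        if b is not None:
            grads.append(gy.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return make_op(y, parents, backward)


_EINSUM_PATHS: dict = {}


def _dw_einsum(expr: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Depthwise einsum with per-signature cached contraction paths.

    Strip kernels (a singleton window axis) run fastest uncontracted; square
    windows benefit from an optimized path, which numpy would otherwise
    re-derive on every call.
    """
    if a.shape[-1] == 1 or a.shape[-2] == 1:
        return np.einsum(expr, a, b)
    key = (expr, a.shape, b.shape)
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(expr, a, b, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(expr, a, b, optimize=path)


def _tap_ranges(k: int, pad: int, stride: int, n_in: int, n_out: int):
    """Output/input index ranges where tap ``t`` of a kernel overlaps the input."""
    out = []
    for t in range(k):
        lo = pad - t
        o_min = max(0, -((-lo) // stride) if lo > 0 else 0)
        o_max = min(n_out - 1, (n_in - 1 + lo) // stride)
        if o_min > o_max:
            out.append(None)
            continue
        i_start = o_min * stride - lo
        out.append((o_min, o_max + 1, i_start, i_start + (o_max - o_min) * stride + 1))
    return out


def _conv_dense(x: Tensor, w: Tensor, b, stride, padding, out_hw) -> Tensor:
    """Dense conv via one stacked channel-GEMM plus shifted accumulation.

    Computes z[tap] = W[tap] @ x for all taps in a single GEMM on the
    *unpadded* input, then adds shifted/strided views of z into the output.
    Avoids im2col materialization entirely.
    """
    sh, sw = stride
    ph, pw = padding
    Ho, Wo = out_hw
    B, C, H, W = x.shape
    Co, _, kh, kw = w.shape
    x3 = x.data.reshape(B, C, H * W)
    wstk = np.ascontiguousarray(w.data.transpose(2, 3, 0, 1)).reshape(kh * kw * Co, C)
    z = np.matmul(wstk[None], x3).reshape(B, kh, kw, Co, H, W)
    rh = _tap_ranges(kh, ph, sh, H, Ho)
    rw = _tap_ranges(kw, pw, sw, W, Wo)
    y = np.zeros((B, Co, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        if rh[i] is None:
            continue
        o0, o1, i0, i1 = rh[i]
        for j in range(kw):
            if rw[j] is None:
                continue
            q0, q1, j0, j1 = rw[j]
            y[:, :, o0:o1, q0:q1] += z[:, i, j, :, i0:i1:sh, j0:j1:sw]
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y += b.data.reshape(1, Co, 1, 1)
        parents.append(b)

    def backward(gy):
        gz = np.zeros((B, kh, kw, Co, H, W), dtype=x.dtype)
        for i in range(kh):
            if rh[i] is None:
                continue
            o0, o1, i0, i1 = rh[i]
            for j in range(kw):
                if rw[j] is None:
                    continue
                q0, q1, j0, j1 = rw[j]
                gz[:, i, j, :, i0:i1:sh, j0:j1:sw] = gy[:, :, o0:o1, q0:q1]
        gz3 = gz.reshape(B, kh * kw * Co, H * W)
        gx = np.matmul(wstk.T[None], gz3).reshape(x.shape)
        gwstk = np.matmul(gz3, x3.transpose(0, 2, 1)).sum(axis=0)
        gw = gwstk.reshape(kh, kw, Co, C).transpose(2, 3, 0, 1)
        grads = [gx, gw]
        if b is not None:
            grads.append(gy.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return make_op(y, parents, backward)


def _conv_grouped(x, xp, w, b, stride, padding, groups, out_hw) -> Tensor:
    """General grouped convolution via im2col (rarely hit; kept for coverage)."""
    sh, sw = stride
    ph, pw = padding
    Ho, Wo = out_hw
    B, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    cols = _im2col(xp, kh, kw, sh, sw, Ho, Wo)
    colsr = cols.reshape(B, groups, Cg * kh * kw, Ho * Wo)
    wr = w.data.reshape(groups, Co // groups, Cg * kh * kw)
    y = np.matmul(wr[None], colsr).reshape(B, Co, Ho, Wo)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        y = y + b.data.reshape(1, Co, 1, 1)
        parents.append(b)

    def backward(gy):
        gyr = gy.reshape(B, groups, Co // groups, Ho * Wo)
        gw = np.matmul(gyr, colsr.transpose(0, 1, 3, 2)).sum(axis=0).reshape(w.shape)
        gcols = np.matmul(wr.transpose(0, 2, 1)[None], gyr).reshape(B, C, kh, kw, Ho, Wo)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += gcols[:, :, i, j]
        gx = gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp
        grads = [gx, gw]
        if b is not None:
            grads.append(gy.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return make_op(y, parents, backward)


def zero_stuff(x, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between spatial samples (transpose-conv helper)."""
    x = as_tensor(x)
    if stride == 1:
        return x
    B, C, H, W = x.shape
    out = np.zeros((B, C, (H - 1) * stride + 1, (W - 1) * stride + 1), dtype=x.dtype)
    out[:, :, ::stride, ::stride] = x.data
    return make_op(out, (x,), lambda g: (g[:, :, ::stride, ::stride],))


def flip_spatial(w) -> Tensor:
    """Flip the last two axes (kernel rotation for transpose convolution)."""
    w = as_tensor(w)
    return make_op(np.ascontiguousarray(w.data[..., ::-1, ::-1]), (w,),
                   lambda g: (g[..., ::-1, ::-1],))


def conv_transpose2d(x, w, b=None, stride: int = 2) -> Tensor:
    """Transpose convolution; ``w``: (Cin, Cout, kh, kw); output (H-1)*s + kh."""
    x, w = as_tensor(x), as_tensor(w)
    _, _, kh, kw = w.shape
    xs = zero_stuff(x, stride)
    wf = flip_spatial(w).transpose((1, 0, 2, 3))
    return conv2d(xs, wf, b, stride=1, padding=(kh - 1, kw - 1))


def bilinear_upsample2x(x) -> Tensor:
    """Fixed-weight 2x bilinear upsampling (depthwise transpose conv)."""
    x = as_tensor(x)
    C = x.shape[1]
    k1 = np.array([1.0, 3.0, 3.0, 1.0], dtype=x.dtype) / 4.0
    k2 = np.outer(k1, k1)
    w = np.zeros((C, 1, 4, 4), dtype=x.dtype)
    w[:, 0] = k2
    xs = zero_stuff(x, 2)
    y = conv2d(xs, Tensor(w), stride=1, padding=3, groups=C)
    # (H-1)*2+1 + 2*3 - 4 + 1 = 2H + 2; crop one pixel from each side
    H2, W2 = 2 * x.shape[2], 2 * x.shape[3]
    return slice2d(y, 1, 1 + H2, 1, 1 + W2)


def slice2d(x, t, b, l, r) -> Tensor:
    """Crop the last two axes to ``[t:b, l:r]``."""
    x = as_tensor(x)
    data = x.data[..., t:b, l:r]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[..., t:b, l:r] = g
        return (gx,)

    return make_op(data, (x,), backward)


# ---------------------------------------------------------------------------
# normalization / activations
# ---------------------------------------------------------------------------

def batch_norm2d(x, gamma, beta, running_mean, running_var, momentum: float,
                 eps: float, training: bool) -> Tensor:
    """Per-channel batch normalization; running stats are updated in place."""
    x = as_tensor(x)
    gamma, beta = as_tensor(gamma), as_tensor(beta)
    C = x.shape[1]
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size // C
        # biased batch variance on purpose: running stats then reproduce the
        # train-mode normalization exactly once re-estimated, instead of
        # drifting by n/(n-1) per layer (ruinous on tiny spatial maps)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    y = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(gy):
        gr = gamma.data.reshape(1, C, 1, 1)
        gbeta = gy.sum(axis=axes)
        ggamma = (gy * xhat).sum(axis=axes)
        if training:
            n = x.data.size // C
            gxhat = gy * gr
            s1 = gxhat.sum(axis=axes).reshape(1, C, 1, 1)
            s2 = (gxhat * xhat).sum(axis=axes).reshape(1, C, 1, 1)
            gx = (inv.reshape(1, C, 1, 1) / n) * (n * gxhat - s1 - xhat * s2)
        else:
            gx = gy * gr * inv.reshape(1, C, 1, 1)
        return (gx, ggamma, gbeta)

    return make_op(y, (x, gamma, beta), backward)


def gelu(x) -> Tensor:
    """Exact GELU: x * Phi(x)."""
    x = as_tensor(x)
    inner = mul(x, 1.0 / np.sqrt(2.0))
    return mul(mul(x, 0.5), add(erf(inner), 1.0))


def softmax(x, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return make_op(p, (x,), backward)


def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy from raw logits.

    ``logits``: (B, K, H, W) or (B, K); ``labels``: integer array (B, H, W) / (B,).
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    x = logits.data
    K = x.shape[1]
    # move class axis last, flatten
    xm = np.moveaxis(x, 1, -1).reshape(-1, K)
    lab = labels.reshape(-1)
    if lab.shape[0] != xm.shape[0]:
        raise ValueError("softmax_cross_entropy: label shape does not match logits")
    zmax = xm.max(axis=1, keepdims=True)
    z = xm - zmax
    lse = np.log(np.exp(z).sum(axis=1)) + zmax[:, 0]
    picked = xm[np.arange(xm.shape[0]), lab]
    loss = (lse - picked).mean()

    def backward(g):
        p = np.exp(xm - lse[:, None])
        p[np.arange(xm.shape[0]), lab] -= 1.0
        p *= g / xm.shape[0]
        gx = np.moveaxis(p.reshape(labels.shape + (K,)), -1, 1).reshape(x.shape)
        return (gx.astype(x.dtype),)

    return make_op(np.asarray(loss, dtype=x.dtype), (logits,), backward)


# ---------------------------------------------------------------------------
# FFT global convolution (the S4-2D application path)
# ---------------------------------------------------------------------------

def fft_causal_conv2d(x, k) -> Tensor:
    """Depthwise causal 2D convolution of ``x`` (B,C,H,W) with kernels ``k`` (C,H,W).

    Zero-pads both operands to at least (2H-1, 2W-1), multiplies spectra and
    keeps the top-left H x W window, i.e. the product of two causal 1D
    convolutions along the axes.
    """
    x, k = as_tensor(x), as_tensor(k)
    B, C, H, W = x.shape
    if k.shape != (C, H, W):
        raise ValueError(f"kernel extent {k.shape} must equal feature extent {(C, H, W)}")
    S1 = _fft.next_fast_len(2 * H - 1)
    S2 = _fft.next_fast_len(2 * W - 1)
    X = _fft.rfft2(x.data, s=(S1, S2))
    Kf = _fft.rfft2(k.data, s=(S1, S2))
    y = _fft.irfft2(X * Kf, s=(S1, S2))[..., :H, :W]

    def backward(gy):
        G = _fft.rfft2(gy, s=(S1, S2))
        gx = _fft.irfft2(np.conj(Kf) * G, s=(S1, S2))[..., :H, :W]
        gk = _fft.irfft2((np.conj(X) * G).sum(axis=0), s=(S1, S2))[..., :H, :W]
        return (gx.astype(x.dtype), gk.astype(k.dtype))

    return make_op(y.astype(x.dtype), (x, k), backward)
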