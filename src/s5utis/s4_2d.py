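"""Two-dimensional S4 kernels and their application to feature maps.

The global 2D kernel is the contraction-weighted sum of outer products of
per-state axis kernels (two independent 1D systems, one per image axis), so
its matrix rank is bounded by the state dimension.  Application is a causal
2D convolution: zero-pad, multiply spectra, keep the top-left window —
exactly the composition of two causal 1D convolutions.

Two layers of API live here:

* pure-NumPy reference ops (:func:`kernel_2d`, :func:`conv2d_global`) used as
  oracles and for debugging dumps;
* :class:`S4Layer2D`, the trainable depthwise layer used inside the encoder
  attention blocks.  It parameterizes each channel by a complex-diagonal
  stable continuous system per axis (initialized from the diagonalized
  normal part of the HiPPO matrix) plus a real contraction vector, and
  re-materializes kernels at the incoming resolution on every forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, atan2, cos, exp, log, mul, reshape, sin, sum_
from .s4_core import DiscreteSSM, dplr_decompose, init_hippo, state_kernels

__all__ = ["FeatureMap", "Kernel2D", "kernel_2d", "kernel_2d_from_axes",
           "conv2d_global", "S4Layer2D", "s4_2d_layer"]


@dataclass
class FeatureMap:
    """Channel-first image tensor (channels, height, width)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"FeatureMap must be (C, H, W), got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all FeatureMap dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FeatureMap contains non-finite values")

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


@dataclass
class Kernel2D:
    """Materialized H x W kernel with its rank-N factorization retained."""

    values: np.ndarray        # (H, W)
    axis_kernels: tuple       # (Kx (N, H), Ky (N, W))
    contraction: np.ndarray   # (N,)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def kernel_2d_from_axes(kx: np.ndarray, ky: np.ndarray, contraction: np.ndarray) -> Kernel2D:
    """Combine per-state axis kernels: values = sum_n c_n outer(kx_n, ky_n)."""
    kx = np.atleast_2d(np.asarray(kx, dtype=float))
    ky = np.atleast_2d(np.asarray(ky, dtype=float))
    c = np.asarray(contraction, dtype=float).ravel()
    if kx.shape[0] != ky.shape[0] or kx.shape[0] != c.shape[0]:
        raise ValueError("axis kernels and contraction must share the state dimension")
    values = np.einsum("n,nh,nw->hw", c, kx, ky, optimize=True)
    return Kernel2D(values=values, axis_kernels=(kx, ky), contraction=c)


def kernel_2d(dssm_x: DiscreteSSM, dssm_y: DiscreteSSM, contraction: np.ndarray,
              H: int, W: int) -> Kernel2D:
    """Materialize the global H x W kernel from two independent axis systems."""
    if H < 1 or W < 1:
        raise ValueError(f"kernel extent must be >= 1, got {(H, W)}")
    kx = state_kernels(dssm_x, H)
    ky = state_kernels(dssm_y, W)
    return kernel_2d_from_axes(kx, ky, contraction)


def conv2d_global(x: FeatureMap, k: Kernel2D) -> FeatureMap:
    """Per-channel causal 2D convolution; kernel extent must equal map extent."""
    if (k.height, k.width) != (x.height, x.width):
        raise ValueError(
            f"kernel extent {(k.height, k.width)} != feature extent "
            f"{(x.height, x.width)}; re-materialize the kernel, never resample"
        )
    H, W = x.height, x.width
    S1 = _fft.next_fast_len(2 * H - 1)
    S2 = _fft.next_fast_len(2 * W - 1)
    Kf = _fft.rfft2(k.values, s=(S1, S2))
    Xf = _fft.rfft2(x.data, s=(S1, S2))
    y = _fft.irfft2(Xf * Kf, s=(S1, S2))[..., :H, :W]
    return FeatureMap(data=y)


# ---------------------------------------------------------------------------
# trainable layer
# ---------------------------------------------------------------------------

class _AxisSSM(nn.Module):
    """Complex-diagonal continuous system for one image axis.

    Per channel c and state n it stores ``lambda = -exp(rho) + i nu`` (strictly
    stable) and a per-channel log step size.  ``materialize(L)`` returns the
    real parts of the per-state kernels ``Re[(Abar^i Bbar)_n]`` as a tensor of
    shape (C, N, L), differentiable in all continuous parameters.
    """

    def __init__(self, channels: int, state_dim: int, rng: np.random.Generator):
        super().__init__()
        lam = dplr_decompose(init_hippo(state_dim)).Lambda
        re = np.clip(-lam.real, 1e-4, None)
        self.rho = nn.Parameter(np.tile(np.log(re), (channels, 1)))
        self.nu = nn.Parameter(np.tile(lam.imag, (channels, 1)))
        self.log_delta = nn.Parameter(
            rng.uniform(np.log(1e-3), np.log(1e-1), size=(channels, 1))
        )
        self.register_buffer("b_vec", np.sqrt(2.0 * np.arange(state_dim) + 1.0)
                             .astype(np.float32))

    def materialize(self, L: int) -> Tensor:
        delta = exp(self.log_delta)                  # (C, 1)
        lam_re = -exp(self.rho)                      # (C, N)
        lam_im = self.nu
        hre = mul(mul(delta, 0.5), lam_re)
        him = mul(mul(delta, 0.5), lam_im)
        d_re = 1.0 - hre
        d_im = -him
        n_re = 1.0 + hre
        n_im = him
        den = d_re * d_re + d_im * d_im
        a_re = (n_re * d_re + n_im * d_im) / den
        a_im = (n_im * d_re - n_re * d_im) / den
        # step-scaled input vector (delta * B) keeps the kernel mass O(1)
        # regardless of the learned step size; the naive reference path in
        # s4_core keeps the unscaled reference form.
        bvec = mul(Tensor(self.b_vec.reshape(1, -1)), delta)
        bb_re = bvec * d_re / den
        bb_im = (-1.0) * bvec * d_im / den
        logmag = mul(log(a_re * a_re + a_im * a_im + 1e-30), 0.5)
        theta = atan2(a_im, a_re)
        C, N = self.rho.shape
        idx = Tensor(np.arange(L, dtype=np.float32).reshape(1, 1, L))
        lm = reshape(logmag, (C, N, 1))
        th = reshape(theta, (C, N, 1))
        mag = exp(idx * lm)                          # (C, N, L)
        phase = idx * th
        kr = reshape(bb_re, (C, N, 1))
        ki = reshape(bb_im, (C, N, 1))
        return mag * (cos(phase) * kr - sin(phase) * ki)


class S4Layer2D(nn.Module):
    """Depthwise global 2D convolution from continuous state-space parameters.

    One independent axis system per image dimension; a real contraction
    vector per channel combines the outer products of the per-state axis
    kernels; an optional learnable feed-through (init 0) adds a direct skip;
    a pointwise 1x1 convolution restores cross-channel mixing (the slot this
    layer occupies originally mixed channels).
    """

    def __init__(self, channels: int, state_dim: int = 16,
                 rng: np.random.Generator | None = None, bidirectional: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels, self.state_dim = channels, state_dim
        self.bidirectional = bidirectional
        self.ssm_x = _AxisSSM(channels, state_dim, rng)
        self.ssm_y = _AxisSSM(channels, state_dim, rng)
        self.contraction = nn.Parameter(
            rng.normal(0.0, 1.0, size=(channels, state_dim)) / state_dim
        )
        self.d_skip = nn.Parameter(np.zeros(channels))
        self.pointwise = nn.Conv2d(channels, channels, 1, rng=rng)

    # -- kernel materialization ---------------------------------------
    def kernel_tensor(self, H: int, W: int) -> Tensor:
        """Differentiable (C, H, W) kernel at the requested extent."""
        kx = self.ssm_x.materialize(H)               # (C, N, H)
        ky = self.ssm_y.materialize(W)               # (C, N, W)
        C, N = self.contraction.shape
        t = reshape(kx, (C, N, H, 1)) * reshape(ky, (C, N, 1, W))
        k = sum_(t * reshape(self.contraction, (C, N, 1, 1)), axis=1)
        if self.bidirectional:
            k = _flip_hw(k)  # summed forward + flipped variant
        return k

    def materialize_kernels(self, H: int, W: int) -> np.ndarray:
        """NumPy snapshot of the per-channel kernels (for tests/debug dumps)."""
        return self.kernel_tensor(H, W).data

    def axis_kernel_arrays(self, H: int, W: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(kx (C,N,H), ky (C,N,W), contraction (C,N)) as NumPy arrays."""
        return (self.ssm_x.materialize(H).data, self.ssm_y.materialize(W).data,
                self.contraction.data.copy())

    # -- application ---------------------------------------------------
    def global_conv(self, x: Tensor) -> Tensor:
        """The depthwise S4-2D convolution alone (no skip, no pointwise mix)."""
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"S4Layer2D expects {self.channels} channels, got {C}")
        k = self.kernel_tensor(H, W)
        return F.fft_causal_conv2d(x, k)

    def forward(self, x: Tensor) -> Tensor:
        y = self.global_conv(x)
        skip = reshape(self.d_skip, (1, self.channels, 1, 1))
        y = y + x * skip
        y = self.pointwise(y)
        if not np.all(np.isfinite(y.data)):
            raise FloatingPointError(
                f"non-finite activations in S4Layer2D(channels={self.channels})"
            )
        return y


def _flip_hw(k: Tensor) -> Tensor:
    from .nn.tensor import make_op
    data = k.data + k.data[..., ::-1, ::-1]
    return make_op(data, (k,), lambda g: (g + g[..., ::-1, ::-1],))


def s4_2d_layer(x: FeatureMap, layer: S4Layer2D) -> FeatureMap:
    """Functional wrapper: run one feature map through a (possibly trained) layer."""
    t = Tensor(x.data[None].astype(np.float32))
    was_training = layer.training
    layer.eval()
    try:
        y = layer(t)
    finally:
        layer.train(was_training)
    return FeatureMap(data=y.data[0].astype(float))
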