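"""One-dimensional structured state-space (S4) machinery.

This module is pure NumPy and holds the reference semantics for everything
downstream: HiPPO initialization of the state matrix, bilinear (Tustin)
discretization, the stepwise recurrence (which doubles as the brute-force
oracle for the convolution path), materialization of the length-L impulse
response kernel, the diagonal-plus-low-rank (DPLR) decomposition, and an
optional Cauchy/generating-function kernel evaluation validated against the
naive construction.

Sign convention: the HiPPO matrix is stored negated relative to the common
"magnitude" presentation, i.e. with ``-(n+1)`` on the diagonal, so that the
continuous system is stable (all eigenvalues have real part <= -1/2) and the
bilinear discretization has spectral radius < 1 for every step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

__all__ = [
    "ContinuousSSM",
    "DiscreteSSM",
    "DPLRParams",
    "Kernel1D",
    "DecompositionError",
    "init_hippo",
    "discretize",
    "ssm_recurrence",
    "ssm_kernel",
    "ssm_kernel_dplr",
    "dplr_decompose",
    "reconstruct_dplr",
    "causal_conv",
]


class DecompositionError(RuntimeError):
    """Raised when the DPLR reconstruction residual exceeds tolerance."""


@dataclass(frozen=True)
class ContinuousSSM:
    """Continuous-time linear system x' = A x + B u, y = C x + D u."""

    A: np.ndarray  # (N, N)
    B: np.ndarray  # (N, 1)
    C: np.ndarray  # (1, N)
    D: float = 0.0

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        N = A.shape[0]
        if A.shape != (N, N):
            raise ValueError(f"A must be square, got {A.shape}")
        B = np.asarray(self.B, dtype=float).reshape(N, 1)
        C = np.asarray(self.C, dtype=float).reshape(1, N)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)

    @property
    def N(self) -> int:
        return self.A.shape[0]

    def is_stable(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.linalg.eigvals(self.A).real <= tol))


@dataclass(frozen=True)
class DiscreteSSM:
    """Bilinear-discretized system; produced by :func:`discretize`."""

    Abar: np.ndarray  # (N, N)
    Bbar: np.ndarray  # (N, 1)
    Cbar: np.ndarray  # (1, N)
    delta: float

    @property
    def N(self) -> int:
        return self.Abar.shape[0]


@dataclass(frozen=True)
class DPLRParams:
    """A = V^-1 (Lambda - (V P)(Q^T V^-1)) V, i.e. A = (normal part) - P Q^T."""

    Lambda: np.ndarray       # (N,) complex
    P: np.ndarray            # (N, r) real
    Q: np.ndarray            # (N, r) real
    V: np.ndarray            # (N, N) complex change of basis
    r: int = 1

    @property
    def N(self) -> int:
        return self.Lambda.shape[0]


@dataclass(frozen=True)
class Kernel1D:
    """Materialized impulse-response kernel: values[i] = Cbar Abar^i Bbar."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    @property
    def L(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# construction and discretization
# ---------------------------------------------------------------------------

def init_hippo(N: int) -> ContinuousSSM:
    """HiPPO (LegS) initialization of (A, B), stored in stabilized (negated) form.

    ``|A[n, k]| = sqrt((2n+1)(2k+1))`` below the diagonal, ``n+1`` on it, zero
    above; ``B[n] = sqrt(2n+1)``.  C defaults to ones.
    """
    if not isinstance(N, (int, np.integer)) or N < 1:
        raise ValueError(f"state dimension must be a positive integer, got {N!r}")
    n = np.arange(N)
    rows = np.sqrt(2.0 * n + 1.0)
    A = -np.outer(rows, rows)
    A = np.tril(A, -1) - np.diag(n + 1.0)
    B = np.sqrt(2.0 * n + 1.0).reshape(N, 1)
    C = np.ones((1, N))
    return ContinuousSSM(A=A, B=B, C=C)


def discretize(ssm: ContinuousSSM, delta: float) -> DiscreteSSM:
    """Bilinear transform: Abar = (I - d/2 A)^-1 (I + d/2 A), Bbar = (I - d/2 A)^-1 B."""
    if delta <= 0:
        raise ValueError(f"step size must be positive, got {delta}")
    N = ssm.N
    eye = np.eye(N)
    M = eye - (delta / 2.0) * ssm.A
    try:
        Abar = np.linalg.solve(M, eye + (delta / 2.0) * ssm.A)
        Bbar = np.linalg.solve(M, ssm.B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs exact singularity
        raise np.linalg.LinAlgError(
            f"(I - delta/2 A) is singular for delta={delta}; cannot discretize"
        ) from exc
    if not (np.all(np.isfinite(Abar)) and np.all(np.isfinite(Bbar))):
        raise np.linalg.LinAlgError(
            f"(I - delta/2 A) is numerically singular for delta={delta}"
        )
    return DiscreteSSM(Abar=Abar, Bbar=Bbar, Cbar=ssm.C.copy(), delta=float(delta))


# ---------------------------------------------------------------------------
# evaluation paths
# ---------------------------------------------------------------------------

def ssm_recurrence(dssm: DiscreteSSM, u: np.ndarray) -> np.ndarray:
    """Stepwise evaluation x_k = Abar x_{k-1} + Bbar u_k, y_k = Cbar x_k, x_{-1} = 0."""
    u = np.asarray(u, dtype=float).ravel()
    y = np.empty_like(u)
    x = np.zeros(dssm.N)
    Ab, Bb, Cb = dssm.Abar, dssm.Bbar.ravel(), dssm.Cbar.ravel()
    for k, uk in enumerate(u):
        x = Ab @ x + Bb * uk
        y[k] = Cb @ x
    return y


def ssm_kernel(dssm: DiscreteSSM, L: int) -> Kernel1D:
    """Materialize values[i] = Cbar Abar^i Bbar by iterated state propagation."""
    if L < 1:
        raise ValueError(f"kernel length must be >= 1, got {L}")
    Cb = dssm.Cbar.ravel()
    v = dssm.Bbar.ravel().copy()
    out = np.empty(L)
    for i in range(L):
        out[i] = Cb @ v
        if i + 1 < L:
            v = dssm.Abar @ v
    return Kernel1D(values=out)


def state_kernels(dssm: DiscreteSSM, L: int) -> np.ndarray:
    """Per-state basis kernels K[n, i] = (Abar^i Bbar)_n, shape (N, L)."""
    if L < 1:
        raise ValueError(f"kernel length must be >= 1, got {L}")
    v = dssm.Bbar.ravel().copy()
    out = np.empty((dssm.N, L))
    for i in range(L):
        out[:, i] = v
        if i + 1 < L:
            v = dssm.Abar @ v
    return out


def causal_conv(u: np.ndarray, k: Kernel1D) -> np.ndarray:
    """Causal convolution y_m = sum_i k[i] u[m-i] via zero-padded real FFT."""
    u = np.asarray(u, dtype=float).ravel()
    if k.L != u.shape[0]:
        raise ValueError(f"kernel length {k.L} != signal length {u.shape[0]}")
    L = u.shape[0]
    if L == 0:
        return u.copy()
    S = _fft.next_fast_len(2 * L - 1)
    y = _fft.irfft(_fft.rfft(u, S) * _fft.rfft(k.values, S), S)[:L]
    return y


# ---------------------------------------------------------------------------
# DPLR decomposition and Cauchy kernel
# ---------------------------------------------------------------------------

def dplr_decompose(ssm: ContinuousSSM, tol: float = 1e-6) -> DPLRParams:
    """Split the (stabilized) HiPPO matrix as A = S - P P^T with normal S.

    With ``P[n] = sqrt(n + 1/2)`` the remainder ``S = A + P P^T`` equals
    ``-I/2`` plus a skew-symmetric matrix, hence is normal and unitarily
    diagonalizable: ``S = W Lambda W^-1``.  Stored with ``V = W^-1`` so that
    the reconstruction identity ``A = V^-1 (Lambda - (V P)(Q^T V^-1)) V``
    holds with Q = P (rank 1).
    """
    A = ssm.A
    N = ssm.N
    p = np.sqrt(np.arange(N) + 0.5).reshape(N, 1)
    S = A + p @ p.T
    lam, W = np.linalg.eig(S)
    V = np.linalg.inv(W)
    params = DPLRParams(Lambda=lam, P=p, Q=p.copy(), V=V, r=1)
    resid = np.linalg.norm(reconstruct_dplr(params) - A) / max(np.linalg.norm(A), 1e-30)
    if resid > tol:
        raise DecompositionError(
            f"DPLR reconstruction residual {resid:.3e} exceeds tolerance {tol:.1e}"
        )
    return params


def reconstruct_dplr(params: DPLRParams) -> np.ndarray:
    """Evaluate A = V^-1 (Lambda - (V P)(Q^T V^-1)) V and return the real part."""
    V = params.V
    Vinv = np.linalg.inv(V)
    inner = np.diag(params.Lambda) - (V @ params.P) @ (params.Q.T @ Vinv)
    A = Vinv @ inner @ V
    if np.abs(A.imag).max() > 1e-6 * max(np.abs(A.real).max(), 1e-30):
        raise DecompositionError("reconstructed A has a non-negligible imaginary part")
    return A.real


def ssm_kernel_dplr(params: DPLRParams, B: np.ndarray, C: np.ndarray,
                    delta: float, L: int) -> Kernel1D:
    """Length-L kernel via the Cauchy/generating-function route (O(L + N) core).

    Works in the diagonalizing basis of the normal part: there the state
    matrix is ``Lambda - p q^T`` with ``p = V P`` and ``q^T = Q^T V^-1``, and
    the truncated generating function at the L-th roots of unity reduces to
    four Cauchy dot products combined through the Woodbury identity.  The
    frequency response is inverted with a single inverse FFT.
    """
    if L < 1:
        raise ValueError(f"kernel length must be >= 1, got {L}")
    if params.r != 1:
        raise NotImplementedError("Cauchy kernel path implemented for rank-1 DPLR")
    V = params.V
    Vinv = np.linalg.inv(V)
    lam = params.Lambda
    p = (V @ params.P).ravel()
    q = (params.Q.T @ Vinv).ravel()          # row vector q^T in the new basis
    b = (V @ np.asarray(B, dtype=float).reshape(-1, 1)).ravel()
    c = (np.asarray(C, dtype=float).reshape(1, -1) @ Vinv).ravel()

    # truncation correction: Ct = C (I - Abar^L) in the diagonal basis
    N = lam.shape[0]
    eye = np.eye(N, dtype=complex)
    Atil = np.diag(lam) - np.outer(p, q)
    M = eye - (delta / 2.0) * Atil
    Abar = np.linalg.solve(M, eye + (delta / 2.0) * Atil)
    Bbar = np.linalg.solve(M, b)
    ct = c @ (eye - np.linalg.matrix_power(Abar, L))

    z = np.exp(-2j * np.pi * np.arange(L) / L)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (2.0 / delta) * (1.0 - z) / (1.0 + z)
        denom = g[:, None] - lam[None, :]
        r00 = np.sum((ct * b)[None, :] / denom, axis=1)
        r01 = np.sum((ct * p)[None, :] / denom, axis=1)
        r10 = np.sum((q * b)[None, :] / denom, axis=1)
        r11 = np.sum((q * p)[None, :] / denom, axis=1)
        khat = (2.0 / (delta * (1.0 + z))) * (r00 - r01 * r10 / (1.0 + r11))
    # z = -1 (L even) hits the bilinear pole; evaluate that frequency densely
    if L % 2 == 0:
        zi = L // 2
        khat[zi] = ct @ np.linalg.solve(eye - z[zi] * Abar, Bbar)
    k = np.fft.ifft(khat, L)
    if np.abs(k.imag).max() > 1e-6 * max(np.abs(k.real).max(), 1e-30):
        raise DecompositionError("Cauchy kernel has a non-negligible imaginary part")
    return Kernel1D(values=k.real)
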