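import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. array x (mutated in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2.0 * eps)
    return g


@pytest.fixture
def gradcheck():
    """Compare autodiff gradients of float64 leaf tensors against central differences."""

    def check(make_loss, *tensors, tol=1e-6):
        loss = make_loss()
        loss.backward()
        for t in tensors:
            assert t.grad is not None, "missing gradient"
            ng = numeric_grad(lambda: make_loss().item(), t.data)
            scale = max(np.abs(ng).max(), 1e-8)
            err = np.abs(t.grad - ng).max() / scale
            assert err < tol, f"gradient mismatch: {err:.3e}"
            t.grad = None

    return check


def random_stable_ssm(rng: np.random.Generator, N: int):
    """A random continuous system with all eigenvalue real parts < 0."""
    from s5utis.s4_core import ContinuousSSM

    M = rng.normal(size=(N, N)) / np.sqrt(N)
    A = M - (np.abs(np.linalg.eigvals(M).real).max() + rng.uniform(0.2, 1.0)) * np.eye(N)
    B = rng.normal(size=(N, 1))
    C = rng.normal(size=(1, N))
    return ContinuousSSM(A=A, B=B, C=C)
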