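"""Layer abstractions on top of the autodiff engine.

Modules discover parameters/submodules through attribute assignment, expose
dotted ``named_parameters`` (used by the ablation parameter audits) and a
``state_dict`` of plain NumPy arrays for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- containers ----------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in getattr(self, "_buffers", {}).items():
            yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        if not hasattr(self, "_buffers"):
            self._buffers: dict[str, np.ndarray] = {}
        self._buffers[name] = value
        setattr(self, name, value)

    # -- mode ----------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing keys: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, b in buffers.items():
            b[...] = state[name]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# concrete layers
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel_size, stride=1, padding=0,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        fan_in = cin // groups * kh * kw
        self.weight = Parameter(_he_init(rng, (cout, cin // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, kernel_size: int = 2, stride: int = 2,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (cin, cout, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride = stride

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.momentum, self.eps, self.training)


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class ReLU(Module):
    def forward(self, x):
        from .tensor import relu
        return relu(x)


class DropPath(Module):
    """Stochastic depth on residual branches (per-sample drop with rescale)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (self.rng.random(shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)
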