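"""Neural-network building blocks on top of the autodiff core.

Initialisation follows the truncated-normal convention (sigma = 0.02, clipped
at two sigma) for weight matrices and zeros for biases; every module takes an
explicit :class:`numpy.random.Generator` so whole models are reproducible from
a single seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T
from .tensor import Tensor

_F32 = np.float32


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    vals = rng.normal(0.0, std, size=shape)
    return np.clip(vals, -2 * std, 2 * std).astype(_F32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny container tracking parameters and submodules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, p.data.copy()) for k, p in self.named_parameters())

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=_F32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {k}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out, dtype=_F32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = T.add(y, self.bias)
        return y


class Conv3d(Module):
    """'Same' 3D convolution over channels-last grids (stride 1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.kernel = kernel
        self.dilation = dilation
        self.weight = Parameter(trunc_normal(rng, (kernel, kernel, kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out, dtype=_F32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias, dilation=self.dilation)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=_F32))
        self.bias = Parameter(np.zeros(dim, dtype=_F32))

    def forward(self, x: Tensor) -> Tensor:
        xn = T.normalize(x, (x.ndim - 1,), self.eps)
        return xn * self.weight + self.bias


class GroupNorm(Module):
    """Group normalisation over a channels-last ``(..., C)`` grid.

    Statistics pool over all leading (spatial) axes and the channels within a
    group, which is the single-sample setting used throughout this package.
    """

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=_F32))
        self.bias = Parameter(np.zeros(channels, dtype=_F32))

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        g = self.groups
        xg = T.reshape(x, shape[:-1] + (g, shape[-1] // g))
        axes = tuple(range(len(shape) - 1)) + (len(shape),)
        xn = T.normalize(xg, axes, self.eps)
        return T.reshape(xn, shape) * self.weight + self.bias


class BatchNorm(Module):
    """Per-channel normalisation using current-sample statistics.

    With a batch size of one (the training protocol here) the statistics pool
    over the spatial axes only; running averages are kept for inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=_F32))
        self.bias = Parameter(np.zeros(channels, dtype=_F32))
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            xn = T.normalize(x, axes, self.eps)
        else:
            xn = (x - self.running_mean) * _F32(1.0) * (self.running_var + self.eps) ** -0.5
        return xn * self.weight + self.bias


class PReLU(Module):
    def __init__(self, channels: int = 1, init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.full(channels, init, dtype=_F32))

    def forward(self, x: Tensor) -> Tensor:
        return T.prelu(x, self.alpha)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def set_training(module: Module, flag: bool):
    if hasattr(module, "training"):
        object.__setattr__(module, "training", flag)
    for sub in module._modules.values():
        set_training(sub, flag)
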