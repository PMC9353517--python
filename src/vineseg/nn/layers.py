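"""Module system and standard layers on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "ConvTranspose2x2", "BatchNorm2d",
           "Linear", "Sequential", "ReLU"]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


class Module:
    """Lightweight container: children and parameters discovered via __dict__."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for mname, m in self._named_modules():
            for bn in getattr(m, "_buffer_names", ()):
                state[f"{mname}{bn}"] = getattr(m, bn).copy()
        return state

    def load_state_dict(self, state: dict, strict: bool = True) -> list[str]:
        """Name-intersection import (the 'loading partial weights' hook);
        returns the list of checkpoint keys that found no matching tensor."""
        own = dict(self.named_parameters())
        bufs = {}
        for mname, m in self._named_modules():
            for bn in getattr(m, "_buffer_names", ()):
                bufs[f"{mname}{bn}"] = (m, bn)
        skipped = []
        for k, arr in state.items():
            if k in own and own[k].data.shape == arr.shape:
                own[k].data = arr.astype(own[k].data.dtype, copy=True)
            elif k in bufs and getattr(bufs[k][0], bufs[k][1]).shape == arr.shape:
                m, bn = bufs[k]
                setattr(m, bn, arr.astype(getattr(m, bn).dtype, copy=True))
            else:
                skipped.append(k)
        if strict and skipped:
            raise KeyError(f"unmatched checkpoint keys: {skipped[:5]}...")
        return skipped


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return core.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2x2(Module):
    """Stride-2 2x2 transposed convolution (the mask-head deconvolution).

    With kernel 2 and stride 2 the windows do not overlap, so the layer is
    exactly a 1x1 convolution to 4*out_ch followed by a periodic
    channel-to-space rearrangement.
    """

    def __init__(self, in_ch: int, out_ch: int, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_ch)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch * 4, in_ch, 1, 1)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch * 4, dtype=dtype))

    def forward(self, x):
        y = core.conv2d(x, self.weight, self.bias)
        return core.pixel_shuffle(y, 2)


class BatchNorm2d(Module):
    """Per-channel normalization with learnable affine.

    `frozen=True` (the tiny-batch training mode) normalizes with the stored
    running statistics instead of batch statistics, so the layer reduces to a
    per-channel affine map with a well-behaved gradient at batch size 2.
    """

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 frozen: bool = False, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch, dtype=dtype))
        self.beta = Parameter(np.zeros(num_ch, dtype=dtype))
        self.running_mean = np.zeros(num_ch, dtype=dtype)
        self.running_var = np.ones(num_ch, dtype=dtype)
        self.eps, self.momentum, self.frozen = eps, momentum, frozen
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.frozen:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return self._normalize_batch(x, mu, var)
        inv = Tensor((1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1).astype(x.dtype))
        mean = Tensor(self.running_mean.reshape(1, -1, 1, 1).astype(x.dtype))
        g4 = self.gamma.reshape(1, -1, 1, 1)
        b4 = self.beta.reshape(1, -1, 1, 1)
        return (x - mean) * inv * g4 + b4

    def _normalize_batch(self, x: Tensor, mu: np.ndarray, var: np.ndarray) -> Tensor:
        # full batch-stats gradient
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = Tensor(self.gamma.data.reshape(1, -1, 1, 1) * xhat + self.beta.data.reshape(1, -1, 1, 1),
                     x.requires_grad or self.gamma.requires_grad, (x, self.gamma, self.beta))
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def bwd(g):
            if self.beta.requires_grad:
                self.beta._accum(g.sum(axis=(0, 2, 3)))
            if self.gamma.requires_grad:
                self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gy = g * self.gamma.data.reshape(1, -1, 1, 1)
                s1 = gy.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gy - s1 / n - xhat * s2 / n) * inv.reshape(1, -1, 1, 1)
                x._accum(dx.astype(x.data.dtype))

        out._backward = bwd
        return out


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)).astype(dtype))
        self.bias = Parameter(np.zeros(out_f, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
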