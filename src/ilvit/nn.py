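"""Minimal neural-network layer library on top of :mod:`ilvit.tensor`.

Initialisation is explicit and seeded: every layer takes a
``numpy.random.Generator`` so that a model built twice from the same seed is
parameter-wise identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Identity",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal samples truncated to ±2 std (re-drawn, not clipped)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    def __init__(self):
        self.training = True

    # parameter discovery walks the attribute dict recursively
    def parameters(self):
        seen = set()
        for p in self._parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def _parameters(self):
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value._parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        yield item
                    elif isinstance(item, Module):
                        yield from item._parameters()

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # simple flat state dict for checkpointing
    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays):
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def append(self, m):
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), std=0.02))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size, rng,
                 stride=1, padding=0, groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = kernel_size if isinstance(kernel_size, (tuple, list)) else (kernel_size,) * 2
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_channels, in_channels // groups, kh, kw))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6, affine: bool = True):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim)) if affine else None
        self.bias = Parameter(np.zeros(dim)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / (var + self.eps).sqrt()
        if self.weight is not None:
            y = y * self.weight + self.bias
        return y
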