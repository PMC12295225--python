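"""Dynamic Inception Convolution (DIC) stem.

The stem replaces a single large-kernel patchify convolution by

1. a *dynamic* strided projection: K candidate kernels are blended per
   sample by a softmax attention computed from globally pooled input
   statistics, and the blended kernel performs one strided convolution to
   the embedding width; followed by
2. an Inception-style depthwise mixer that splits channels into four
   branches — a small square kernel, a horizontal band kernel, a vertical
   band kernel and an identity map — and concatenates them back.

The pair of orthogonal band kernels (1×kb and kb×1) approximates the
receptive field of a large square kernel at a fraction of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tensor import Parameter, Tensor

__all__ = [
    "DICConfig",
    "DynamicKernelBank",
    "kernel_attention",
    "aggregate_and_convolve",
    "InceptionMix",
    "inception_mix",
    "DICStem",
]


@dataclass
class DICConfig:
    """Configuration of the DIC stem.

    branch_ratios are the channel shares of the square / horizontal-band /
    vertical-band / identity branches and must sum to 1 with integer
    channel counts.
    """

    in_channels: int = 3
    embed_dim: int = 96
    num_kernels: int = 4          # K candidate kernels in the dynamic bank
    small_kernel: int = 3         # ks, square branch (and the projection kernel)
    band_kernel: int = 11         # kb, band branches
    branch_ratios: tuple = (1 / 8, 1 / 8, 1 / 8, 5 / 8)
    stem_stride: int = 4
    attn_reduction: int = 4       # bottleneck of the kernel-attention subnet

    def __post_init__(self):
        if self.small_kernel % 2 == 0 or self.band_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd for 'same' padding")
        if self.small_kernel > self.band_kernel:
            raise ValueError("small_kernel must not exceed band_kernel")
        if abs(sum(self.branch_ratios) - 1.0) > 1e-9 or len(self.branch_ratios) != 4:
            raise ValueError("branch_ratios must be four fractions summing to 1")

    def branch_channels(self, channels: int) -> tuple:
        counts = [int(round(r * channels)) for r in self.branch_ratios[:3]]
        counts.append(channels - sum(counts))
        if any(c < 0 for c in counts) or sum(counts) != channels:
            raise ValueError(f"branch_ratios {self.branch_ratios} do not split "
                             f"{channels} channels into integers")
        return tuple(counts)


class DynamicKernelBank(nn.Module):
    """K stacked convolution kernels plus the attention subnet over them.

    The attention subnet is two affine maps applied to globally averaged
    input channels, then a softmax over the K kernels (temperature 1).
    There is no nonlinearity between the two maps.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, num_kernels: int = 4, stride: int = 1,
                 padding: int = 0, groups: int = 1, attn_reduction: int = 4,
                 bias: bool = True):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.num_kernels = num_kernels
        self.stride, self.padding, self.groups = stride, padding, groups
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.kernels = Parameter(rng.uniform(
            -bound, bound, size=(num_kernels, out_channels, in_channels // groups, k, k)))
        hidden = max(in_channels // attn_reduction, 4)
        self.fc1 = nn.Linear(in_channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, num_kernels, rng)
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w = kernel_attention(x, self)
        return aggregate_and_convolve(x, self, w)


def kernel_attention(x: Tensor, bank: DynamicKernelBank) -> Tensor:
    """Per-sample softmax weights over the bank's K kernels, shape (N, K)."""
    if x.shape[1] != bank.in_channels:
        raise ValueError(f"channel mismatch: bank expects {bank.in_channels} "
                         f"input channels, got {x.shape[1]}")
    pooled = x.mean(axis=(2, 3))          # (N, C) global average pool
    logits = bank.fc2(bank.fc1(pooled))   # two affine maps, no nonlinearity
    return logits.softmax(axis=-1)


def aggregate_and_convolve(x: Tensor, bank: DynamicKernelBank, weights: Tensor) -> Tensor:
    """Convolve each sample with its weight-blended kernel Σ_k w_k · W_k."""
    n, k = weights.shape
    if k != bank.num_kernels:
        raise ValueError(f"expected {bank.num_kernels} weights per sample, got {k}")
    kflat = bank.kernels.reshape(bank.num_kernels, -1)        # (K, P)
    blended = (weights @ kflat).reshape((n,) + bank.kernels.shape[1:])
    return x.conv2d(blended, bank.bias, stride=bank.stride,
                    padding=bank.padding, groups=bank.groups)


class InceptionMix(nn.Module):
    """Four-branch depthwise mixer: ks×ks / 1×kb / kb×1 / identity."""

    def __init__(self, channels: int, cfg: DICConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.splits = cfg.branch_channels(channels)
        c_sq, c_h, c_v, _ = self.splits
        ks, kb = cfg.small_kernel, cfg.band_kernel
        self.conv_square = nn.Conv2d(c_sq, c_sq, ks, rng, padding=ks // 2, groups=c_sq)
        self.conv_hband = nn.Conv2d(c_h, c_h, (1, kb), rng, padding=(0, kb // 2), groups=c_h)
        self.conv_vband = nn.Conv2d(c_v, c_v, (kb, 1), rng, padding=(kb // 2, 0), groups=c_v)

    def forward(self, x: Tensor) -> Tensor:
        c_sq, c_h, c_v, c_id = self.splits
        i1, i2, i3 = c_sq, c_sq + c_h, c_sq + c_h + c_v
        parts = [
            self.conv_square(x[:, :i1]),
            self.conv_hband(x[:, i1:i2]),
            self.conv_vband(x[:, i2:i3]),
            x[:, i3:],                      # identity branch, bit-identical
        ]
        return Tensor.concat(parts, axis=1)


def inception_mix(x: Tensor, mix: InceptionMix) -> Tensor:
    return mix(x)


class DICStem(nn.Module):
    """Dynamic strided projection to ``embed_dim`` followed by the
    Inception mixer; 224×224 inputs become 56×56 at the default stride 4."""

    def __init__(self, cfg: DICConfig, rng: np.random.Generator,
                 dynamic_projection: bool = True):
        super().__init__()
        self.cfg = cfg
        ks = cfg.small_kernel
        if dynamic_projection:
            self.proj = DynamicKernelBank(
                cfg.in_channels, cfg.embed_dim, ks, rng,
                num_kernels=cfg.num_kernels, stride=cfg.stem_stride,
                padding=ks // 2, attn_reduction=cfg.attn_reduction)
        else:
            self.proj = nn.Conv2d(cfg.in_channels, cfg.embed_dim, ks, rng,
                                  stride=cfg.stem_stride, padding=ks // 2)
        self.mix = InceptionMix(cfg.embed_dim, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        s = self.cfg.stem_stride
        if h % s or w % s:
            raise ValueError(f"input spatial dims ({h},{w}) not divisible by "
                             f"stem stride {s}")
        return self.mix(self.proj(x))


def dic_stem(x: Tensor, stem: DICStem) -> Tensor:
    return stem(x)
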