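"""Omni-Dimensional Dynamic Convolution (ODC).

A bank of ``n`` candidate kernels is modulated along four kernel
dimensions by sigmoid attention factors computed from globally pooled
input statistics:

    y = (α_w1·α_f1·α_c1·α_s1·W_1 + … + α_wn·α_fn·α_cn·α_sn·W_n) * x

where α_s spans the kh·kw spatial taps, α_c the per-group input channels,
α_f the output channels (filters) and α_w the kernel index.  All four
factors come from one shared GAP → FC → ReLU trunk with four affine heads
followed by an element-wise sigmoid, so each factor lies strictly in
(0, 1).  The effective kernel is assembled per sample and applied as a
single convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Parameter, Tensor

__all__ = ["ODCConfig", "ODConv2d", "odc_attentions", "odc_forward"]


@dataclass
class ODCConfig:
    in_channels: int = 4
    out_channels: int = 4
    kernel_size: int = 3
    num_kernels: int = 4      # n candidate kernels
    reduction: int = 16       # attention bottleneck ratio
    groups: int = 1
    kernel_softmax: bool = False   # softmax (instead of sigmoid) on the kernel-wise factor

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("channels must be divisible by groups")


class ODConv2d(nn.Module):
    def __init__(self, cfg: ODCConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        k = cfg.kernel_size
        cin_g = cfg.in_channels // cfg.groups
        fan_in = cin_g * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.kernels = Parameter(rng.uniform(
            -bound, bound,
            size=(cfg.num_kernels, cfg.out_channels, cin_g, k, k)))
        self.bias = Parameter(np.zeros(cfg.out_channels))
        hidden = max(cfg.in_channels // cfg.reduction, 4)
        self.fc1 = nn.Linear(cfg.in_channels, hidden, rng)
        self.head_spatial = nn.Linear(hidden, k * k, rng)
        self.head_channel = nn.Linear(hidden, cin_g, rng)
        self.head_filter = nn.Linear(hidden, cfg.out_channels, rng)
        self.head_kernel = nn.Linear(hidden, cfg.num_kernels, rng)
        # open the sigmoid gates at init (σ(2) ≈ 0.88): four nearly-closed
        # gates would otherwise scale the assembled kernel by ~0.5^4
        for head in (self.head_spatial, self.head_channel,
                     self.head_filter, self.head_kernel):
            head.bias.data += 2.0

    def forward(self, x: Tensor) -> Tensor:
        return odc_forward(x, self)


def odc_attentions(x: Tensor, conv: ODConv2d):
    """Four attention factor sets, each in (0,1), one per batch element.

    Returns ``(alpha_s, alpha_c, alpha_f, alpha_w)`` with shapes
    ``(N, kh·kw)``, ``(N, C_in/groups)``, ``(N, C_out)``, ``(N, n)``.
    """
    cfg = conv.cfg
    if x.shape[1] != cfg.in_channels:
        raise ValueError(f"channel mismatch: ODC expects {cfg.in_channels} "
                         f"input channels, got {x.shape[1]}")
    trunk = conv.fc1(x.mean(axis=(2, 3))).relu()
    alpha_s = conv.head_spatial(trunk).sigmoid()
    alpha_c = conv.head_channel(trunk).sigmoid()
    alpha_f = conv.head_filter(trunk).sigmoid()
    logits_w = conv.head_kernel(trunk)
    alpha_w = logits_w.softmax(axis=-1) if cfg.kernel_softmax else logits_w.sigmoid()
    return alpha_s, alpha_c, alpha_f, alpha_w


def odc_forward(x: Tensor, conv: ODConv2d, factors=None) -> Tensor:
    """Assemble the per-sample effective kernel and convolve once.

    ``factors`` lets callers inject precomputed ``(α_s, α_c, α_f, α_w)``
    (used by the equivalence oracles); by default they are computed from
    ``x`` itself.
    """
    cfg = conv.cfg
    if factors is None:
        factors = odc_attentions(x, conv)
    alpha_s, alpha_c, alpha_f, alpha_w = factors
    n = x.shape[0]
    k = cfg.kernel_size
    # broadcast each factor onto its kernel dimension:
    #   kernels: (n_k, C_out, C_in/g, kh, kw);  sample axis prepended
    a_s = alpha_s.reshape(n, 1, 1, 1, k, k)
    a_c = alpha_c.reshape(n, 1, 1, cfg.in_channels // cfg.groups, 1, 1)
    a_f = alpha_f.reshape(n, 1, cfg.out_channels, 1, 1, 1)
    a_w = alpha_w.reshape(n, cfg.num_kernels, 1, 1, 1, 1)
    kernels = conv.kernels.reshape((1,) + conv.kernels.shape)
    weighted = kernels * a_s * a_c * a_f * a_w          # (N, n_k, C_out, C_in/g, kh, kw)
    combined = weighted.sum(axis=1)                     # per-sample effective kernel
    return x.conv2d(combined, conv.bias, stride=1, padding=k // 2, groups=cfg.groups)
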