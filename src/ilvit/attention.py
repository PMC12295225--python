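"""Pooling attention, activation-gated linear attention, and the COKA block.

Two token mixers share one multi-head skeleton with strided depthwise
pooling of queries / keys / values (the multiscale-transformer mechanism
that downsamples inside attention):

* softmax attention — ``softmax(QKᵀ/√d_k)·V`` (the baseline mixer);
* linear attention — ``σ(Q)·(σ(Kᵀ)·softmax(V))/√d_k`` evaluated
  right-to-left, so the key–value summary is aggregated first and the
  cost is linear in token count.  The softmax acts over each value
  token's feature axis, which is what keeps the O(L) evaluation order
  valid (a token-axis softmax is available behind ``v_softmax_axis``).

A :class:`Block` assembles one transformer stage element: (Contra)Norm →
optional omni-dimensional dynamic convolution → attention → residual →
(Contra)Norm → feed-forward (MLP or KAN) → residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .kan import KANMixer
from .norm_quant import ContraNorm, ContraNormConfig
from .odc import ODCConfig, ODConv2d
from .tensor import Tensor

__all__ = ["AttentionConfig", "linear_attention", "MultiHeadPooledAttention",
           "Block", "BlockConfig"]


@dataclass
class AttentionConfig:
    embed_dim: int = 96            # input width d_in
    dim_out: int = 96              # output width (doubles at stage transitions)
    num_heads: int = 1
    qkv_bias: bool = True
    q_stride: int = 1              # strided pooling of queries (stage transitions)
    kv_stride: int = 1             # strided pooling of keys/values
    attn_type: str = "softmax"     # "softmax" | "linear"
    v_softmax_axis: str = "feature"  # "feature" (per token) | "token"

    def __post_init__(self):
        if self.dim_out % self.num_heads:
            raise ValueError("dim_out must be divisible by num_heads")

    @property
    def head_dim(self) -> int:
        return self.dim_out // self.num_heads


def linear_attention(q: Tensor, k: Tensor, v: Tensor, d_k: int,
                     v_softmax_axis: str = "feature") -> Tensor:
    """Activation-gated linear attention on per-head token arrays.

    ``q``: (..., L_q, d_k); ``k``, ``v``: (..., L_kv, d_k).  Output is
    ``σ(Q)·(σ(Kᵀ)·softmax(V))/√d_k`` — the (d_k × d_k) key–value summary
    is formed first, so cost grows linearly with token count.
    """
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(f"key/value token counts differ: {k.shape[-2]} vs {v.shape[-2]}")
    axis = -1 if v_softmax_axis == "feature" else -2
    summary = k.sigmoid().swapaxes(-1, -2) @ v.softmax(axis=axis)   # (..., d_k, d_k)
    return (q.sigmoid() @ summary) * (1.0 / np.sqrt(d_k))


def _tokens_to_grid(x: Tensor, hw) -> Tensor:
    b, l, c = x.shape
    h, w = hw
    return x.reshape((b, h, w, c)).transpose(0, 3, 1, 2)


def _grid_to_tokens(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape((b, h * w, c))


class MultiHeadPooledAttention(nn.Module):
    """Per-head projections, depthwise pooling convs, token mixing, output
    projection.  A pooled-query residual is added inside the mixer."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d_in, d_out = cfg.embed_dim, cfg.dim_out
        self.wq = nn.Linear(d_in, d_out, rng, bias=cfg.qkv_bias)
        self.wk = nn.Linear(d_in, d_out, rng, bias=cfg.qkv_bias)
        self.wv = nn.Linear(d_in, d_out, rng, bias=cfg.qkv_bias)
        self.pool_q = nn.Conv2d(d_out, d_out, 3, rng, stride=cfg.q_stride,
                                padding=1, groups=d_out, bias=False)
        self.pool_k = nn.Conv2d(d_out, d_out, 3, rng, stride=cfg.kv_stride,
                                padding=1, groups=d_out, bias=False)
        self.pool_v = nn.Conv2d(d_out, d_out, 3, rng, stride=cfg.kv_stride,
                                padding=1, groups=d_out, bias=False)
        self.proj = nn.Linear(d_out, d_out, rng)

    def _project(self, x, hw, linear, pool):
        y = _tokens_to_grid(linear(x), hw)
        y = pool(y)
        hw_out = (y.shape[2], y.shape[3])
        tokens = _grid_to_tokens(y)
        b, l, _ = tokens.shape
        h = self.cfg.num_heads
        heads = tokens.reshape((b, l, h, self.cfg.head_dim)).transpose(0, 2, 1, 3)
        return heads, hw_out

    def forward(self, x: Tensor, hw):
        cfg = self.cfg
        q, hw_q = self._project(x, hw, self.wq, self.pool_q)
        k, _ = self._project(x, hw, self.wk, self.pool_k)
        v, _ = self._project(x, hw, self.wv, self.pool_v)
        if cfg.attn_type == "softmax":
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(cfg.head_dim))
            out = scores.softmax(axis=-1) @ v
        elif cfg.attn_type == "linear":
            out = linear_attention(q, k, v, cfg.head_dim, cfg.v_softmax_axis)
        else:
            raise ValueError(f"unknown attention type {cfg.attn_type!r}")
        out = out + q                                   # pooled-query residual
        b, h, lq, dk = out.shape
        merged = out.transpose(0, 2, 1, 3).reshape((b, lq, h * dk))
        return self.proj(merged), hw_q


@dataclass
class BlockConfig:
    dim: int = 96                   # d_in
    dim_out: int = 96
    num_heads: int = 1
    q_stride: int = 1
    kv_stride: int = 1
    attn_type: str = "softmax"
    use_odc: bool = False
    norm: str = "ln"                # "ln" | "contranorm"
    ffn: str = "mlp"                # "mlp" | "kan"
    mlp_ratio: float = 4.0
    contranorm_scale: float = 0.1
    odc_num_kernels: int = 4
    odc_group_width: int | None = None    # channels per group (None → dense)
    odc_reduction: int = 16
    kan_mode: str = "channelwise"
    kan_width: int | None = None
    kan_grid_size: int = 5
    kan_spline_order: int = 3

    def odc_groups(self) -> int:
        if self.odc_group_width is None:
            return 1
        return max(1, self.dim // min(self.odc_group_width, self.dim))


class Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).gelu())


class Block(nn.Module):
    """One ladder block; residual paths follow the pre-norm layout

    ``x' = skip(x) + Attn(ODC(Norm1(x)))``; ``y = x' + FFN(Norm2(x'))``.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg

        def make_norm(dim):
            if cfg.norm == "contranorm":
                return ContraNorm(dim, ContraNormConfig(scale=cfg.contranorm_scale))
            return nn.LayerNorm(dim)

        self.norm1 = make_norm(cfg.dim)
        if cfg.use_odc:
            self.odc = ODConv2d(ODCConfig(
                in_channels=cfg.dim, out_channels=cfg.dim, kernel_size=3,
                num_kernels=cfg.odc_num_kernels, reduction=cfg.odc_reduction,
                groups=cfg.odc_groups()), rng)
        else:
            self.odc = None
        self.attn = MultiHeadPooledAttention(AttentionConfig(
            embed_dim=cfg.dim, dim_out=cfg.dim_out, num_heads=cfg.num_heads,
            q_stride=cfg.q_stride, kv_stride=cfg.kv_stride,
            attn_type=cfg.attn_type), rng)
        self.skip_proj = (nn.Linear(cfg.dim, cfg.dim_out, rng)
                          if cfg.dim != cfg.dim_out else None)
        self.norm2 = make_norm(cfg.dim_out)
        if cfg.ffn == "mlp":
            self.ffn = Mlp(cfg.dim_out, int(cfg.dim_out * cfg.mlp_ratio), rng)
        elif cfg.ffn == "kan":
            self.ffn = KANMixer(cfg.dim_out, rng, mode=cfg.kan_mode,
                                width=cfg.kan_width, grid_size=cfg.kan_grid_size,
                                spline_order=cfg.kan_spline_order)
        else:
            raise ValueError(f"unknown ffn type {cfg.ffn!r}")

    def forward(self, x: Tensor, hw):
        cfg = self.cfg
        xn = self.norm1(x)
        if self.odc is not None:
            xn = _grid_to_tokens(self.odc(_tokens_to_grid(xn, hw)))
        attn_out, hw_out = self.attn(xn, hw)
        skip = self.skip_proj(x) if self.skip_proj is not None else x
        if cfg.q_stride > 1:
            skip = _grid_to_tokens(_tokens_to_grid(skip, hw).avg_pool2d(cfg.q_stride))
        x1 = skip + attn_out
        y = x1 + self.ffn(self.norm2(x1))
        return y, hw_out
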