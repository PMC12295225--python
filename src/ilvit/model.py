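"""ILViT model assembly, the ablation ladder, and the efficiency profiler.

The ladder shares one four-stage, ten-block multiscale skeleton
(depths [1, 2, 5, 2], widths 96→768, heads 1→8, stride-4 stem) and swaps
components cumulatively:

=========  ==============================================================
variant    composition
=========  ==============================================================
baseline   7×7 conv stem + softmax pooling-attention blocks with MLP
V0         baseline with the Dynamic Inception Convolution stem
V1         V0 with activation-gated linear attention
V2         V1 with omni-dimensional dynamic convolution before attention
V3         V2 with contrastive normalization (blocks and tail)
V4         V3 with KAN feed-forward and quantized tail (= ILViT)
=========  ==============================================================

The profiler reports trainable parameters and forward multiply–accumulate
counts (1 MAC = 1 FLOP) at a stated input shape.  The default counting
convention covers convolution and affine-map MACs only — attention
score/value products, normalizations and element-wise ops are excluded —
and is switchable via ``include_attention``.  Parameter counts are always
full precision; quantization is a bit-width reduction, not a parameter
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .attention import Block, BlockConfig
from .dic import DICConfig, DICStem
from .norm_quant import ContraNorm, ContraNormConfig, QAct, QuantLinear
from .tensor import Tensor

__all__ = ["ModelConfig", "ILViT", "build_model", "count_parameters",
           "count_flops", "profile_model", "ProfileReport", "VARIANTS",
           "ilvit_default_config", "tiny_test_config"]

VARIANTS = ("baseline", "V0", "V1", "V2", "V3", "V4")

# cumulative feature switches along the ladder
_LADDER = {
    "baseline": dict(stem="conv", attn="softmax", odc=False, norm="ln", ffn="mlp", quant=False),
    "V0":       dict(stem="dic", attn="softmax", odc=False, norm="ln", ffn="mlp", quant=False),
    "V1":       dict(stem="dic", attn="linear", odc=False, norm="ln", ffn="mlp", quant=False),
    "V2":       dict(stem="dic", attn="linear", odc=True, norm="ln", ffn="mlp", quant=False),
    "V3":       dict(stem="dic", attn="linear", odc=True, norm="contranorm", ffn="mlp", quant=False),
    "V4":       dict(stem="dic", attn="linear", odc=True, norm="contranorm", ffn="kan", quant=True),
}


@dataclass
class ModelConfig:
    """Complete architectural description; a config + seed rebuilds a model
    bit-identically."""

    variant: str = "V4"
    num_classes: int = 4
    image_size: int = 224
    stage_depths: tuple = (1, 2, 5, 2)
    embed_dims: tuple = (96, 192, 384, 768)
    stage_heads: tuple = (1, 2, 4, 8)
    mlp_ratio: float = 4.0
    stem_stride: int = 4
    baseline_stem_kernel: int = 7
    dic: DICConfig = field(default_factory=DICConfig)
    odc_num_kernels: int = 2
    odc_group_width: int = 24
    odc_reduction: int = 16
    contranorm_scale: float = 0.1
    kan_mode: str = "channelwise"
    kan_width: int | None = None
    kan_grid_size: int = 5
    kan_spline_order: int = 3
    quant_bits: int = 8
    kv_res_ceiling: int | None = None   # None → image_size // 16

    def __post_init__(self):
        if self.variant == "ilvit":
            self.variant = "V4"
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {list(VARIANTS)}")
        if len(self.stage_depths) != len(self.embed_dims) or \
           len(self.stage_depths) != len(self.stage_heads):
            raise ValueError("stage_depths, embed_dims and stage_heads must align")
        self.dic.embed_dim = self.embed_dims[0]
        self.dic.stem_stride = self.stem_stride

    @property
    def depth(self) -> int:
        return int(sum(self.stage_depths))

    def block_plan(self):
        """Per-block (dim_in, dim_out, heads, q_stride, kv_stride, res_in).

        Keys/values are pooled to a ceiling of (image/16)² tokens and never
        finer than the query grid; queries pool 2× at each stage entry.
        """
        feats = _LADDER[self.variant]
        res = self.image_size // self.stem_stride
        kv_ceiling = self.kv_res_ceiling or max(1, self.image_size // 16)
        plan = []
        for stage, depth in enumerate(self.stage_depths):
            for j in range(depth):
                first = j == 0 and stage > 0
                dim_in = self.embed_dims[stage - 1] if first else self.embed_dims[stage]
                dim_out = self.embed_dims[stage]
                q_stride = 2 if first else 1
                res_q = res // q_stride
                kv_res = min(kv_ceiling, res_q)
                kv_stride = max(1, res // kv_res)
                plan.append(BlockConfig(
                    dim=dim_in, dim_out=dim_out, num_heads=self.stage_heads[stage],
                    q_stride=q_stride, kv_stride=kv_stride,
                    attn_type=feats["attn"], use_odc=feats["odc"], norm=feats["norm"],
                    ffn=feats["ffn"], mlp_ratio=self.mlp_ratio,
                    contranorm_scale=self.contranorm_scale,
                    odc_num_kernels=self.odc_num_kernels,
                    odc_group_width=self.odc_group_width,
                    odc_reduction=self.odc_reduction,
                    kan_mode=self.kan_mode, kan_width=self.kan_width,
                    kan_grid_size=self.kan_grid_size,
                    kan_spline_order=self.kan_spline_order))
                res = res_q
        return plan

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stage_depths", "embed_dims", "stage_heads"):
            d[key] = list(d[key])
        d["dic"]["branch_ratios"] = list(d["dic"]["branch_ratios"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "dic" in d and isinstance(d["dic"], dict):
            dic = dict(d["dic"])
            if "branch_ratios" in dic:
                dic["branch_ratios"] = tuple(dic["branch_ratios"])
            d["dic"] = DICConfig(**dic)
        for key in ("stage_depths", "embed_dims", "stage_heads"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class ILViT(nn.Module):
    """The assembled classifier: stem → block stack → norm → GAP → head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        feats = _LADDER[cfg.variant]
        d0 = cfg.embed_dims[0]
        if feats["stem"] == "dic":
            self.stem = DICStem(cfg.dic, rng)
        else:
            k = cfg.baseline_stem_kernel
            self.stem = nn.Conv2d(3, d0, k, rng, stride=cfg.stem_stride, padding=k // 2)
        self.blocks = nn.ModuleList([Block(bc, rng) for bc in self.block_plan_cache()])
        d_last = cfg.embed_dims[-1]
        if feats["norm"] == "contranorm":
            self.final_norm = ContraNorm(d_last, ContraNormConfig(cfg.contranorm_scale))
        else:
            self.final_norm = nn.LayerNorm(d_last)
        if feats["quant"]:
            self.tail_act = QAct(cfg.quant_bits)
            self.head = QuantLinear(d_last, cfg.num_classes, rng, bit_width=cfg.quant_bits)
        else:
            self.tail_act = None
            self.head = nn.Linear(d_last, cfg.num_classes, rng)

    def block_plan_cache(self):
        if not hasattr(self, "_plan"):
            self._plan = self.cfg.block_plan()
        return self._plan

    def forward(self, x: Tensor) -> Tensor:
        """Logits for a normalized NCHW image batch."""
        z = self.stem(x)
        b, c, h, w = z.shape
        tokens = z.transpose(0, 2, 3, 1).reshape((b, h * w, c))
        hw = (h, w)
        for block in self.blocks:
            tokens, hw = block(tokens, hw)
        tokens = self.final_norm(tokens)
        pooled = tokens.mean(axis=1)
        if self.tail_act is not None:
            pooled = self.tail_act(pooled)
        return self.head(pooled)


def build_model(cfg: ModelConfig, seed: int = 0) -> ILViT:
    """Deterministic construction: same config + seed → identical weights."""
    return ILViT(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """All trainable weights, full precision."""
    return model.n_params()


# --------------------------------------------------------------------------
# analytic profiler
# --------------------------------------------------------------------------

@dataclass
class ProfileReport:
    variant: str
    input_shape: tuple
    total_params: int
    total_flops: int
    breakdown: list            # (name, params, flops)

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def flops_g(self) -> float:
        return self.total_flops / 1e9

    def table(self) -> str:
        lines = [f"{'module':<14}{'params':>12}{'MFLOPs':>12}"]
        for name, p, f in self.breakdown:
            lines.append(f"{name:<14}{p:>12,}{f / 1e6:>12.2f}")
        lines.append(f"{'total':<14}{self.total_params:>12,}{self.total_flops / 1e6:>12.2f}")
        lines.append(f"=> {self.params_m:.2f} M params, {self.flops_g:.2f} GFLOPs")
        return "\n".join(lines)


def _conv_flops(l_out: int, c_out: int, c_in_per_group: int, kh: int, kw: int) -> int:
    return l_out * c_out * c_in_per_group * kh * kw


def _block_flops(model_cfg: ModelConfig, bc: BlockConfig, res_in: int,
                 include_attention: bool) -> int:
    l_in = res_in * res_in
    res_q = (res_in - 1) // bc.q_stride + 1
    l_q = res_q * res_q
    kv_res = (res_in - 1) // bc.kv_stride + 1
    l_kv = kv_res * kv_res
    d_in, d_out = bc.dim, bc.dim_out
    f = 0
    if bc.use_odc:
        groups = bc.odc_groups()
        cin_g = d_in // groups
        f += _conv_flops(l_in, d_in, cin_g, 3, 3)
        hidden = max(d_in // bc.odc_reduction, 4)
        f += d_in * hidden
        f += hidden * (9 + cin_g + d_in + bc.odc_num_kernels)
    f += 3 * l_in * d_in * d_out                       # q, k, v projections
    f += _conv_flops(l_q, d_out, 1, 3, 3)              # depthwise pools
    f += 2 * _conv_flops(l_kv, d_out, 1, 3, 3)
    if include_attention:
        dk = d_out // bc.num_heads
        if bc.attn_type == "softmax":
            f += 2 * l_q * l_kv * d_out
        else:
            f += (l_q + l_kv) * dk * d_out
    f += l_q * d_out * d_out                           # output projection
    if d_in != d_out:
        f += l_in * d_in * d_out                       # shortcut projection
    if bc.ffn == "mlp":
        hidden = int(d_out * bc.mlp_ratio)
        f += 2 * l_q * d_out * hidden
    else:
        m = bc.kan_grid_size + bc.kan_spline_order + 2  # MACs per edge
        if bc.kan_mode == "channelwise":
            f += l_q * d_out * m
        elif bc.kan_mode == "bottleneck":
            f += l_q * 2 * d_out * bc.kan_width * m
        else:
            f += l_q * d_out * d_out * m
    return f


def profile_model(model: ILViT, input_hw: int | None = None,
                  include_attention: bool = False) -> ProfileReport:
    """Parameters and forward MACs for one image at ``input_hw``².

    Parameters are summed from the live modules; FLOPs come from the
    closed-form per-layer counts under the documented convention.
    """
    cfg = model.cfg
    size = input_hw or cfg.image_size
    if size % cfg.stem_stride:
        raise ValueError("input size must be divisible by the stem stride")
    breakdown = []
    res = size // cfg.stem_stride
    l0 = res * res
    if isinstance(model.stem, DICStem):
        dic = cfg.dic
        ks, kb = dic.small_kernel, dic.band_kernel
        c_sq, c_h, c_v, _ = dic.branch_channels(dic.embed_dim)
        f = _conv_flops(l0, dic.embed_dim, 3, ks, ks)
        hidden = max(3 // dic.attn_reduction, 4)
        f += 3 * hidden + hidden * dic.num_kernels
        f += _conv_flops(l0, c_sq, 1, ks, ks)
        f += _conv_flops(l0, c_h, 1, 1, kb) + _conv_flops(l0, c_v, 1, kb, 1)
    else:
        k = cfg.baseline_stem_kernel
        f = _conv_flops(l0, cfg.embed_dims[0], 3, k, k)
    breakdown.append(("stem", model.stem.n_params(), f))
    plan = model.block_plan_cache()
    for i, (bc, block) in enumerate(zip(plan, model.blocks)):
        bf = _block_flops(cfg, bc, res, include_attention)
        breakdown.append((f"block{i}", block.n_params(), bf))
        res = (res - 1) // bc.q_stride + 1
    head_params = model.final_norm.n_params() + model.head.n_params()
    head_flops = cfg.embed_dims[-1] * cfg.num_classes
    breakdown.append(("head", head_params, head_flops))
    total_p = sum(p for _, p, _ in breakdown)
    total_f = sum(fl for _, _, fl in breakdown)
    assert total_p == model.n_params()      # breakdown must sum exactly
    return ProfileReport(cfg.variant, (3, size, size), total_p, total_f, breakdown)


def count_flops(model: ILViT, input_hw: int | None = None,
                include_attention: bool = False) -> int:
    """Forward multiply–accumulate count (1 MAC = 1 FLOP) for one image."""
    return profile_model(model, input_hw, include_attention).total_flops


# --------------------------------------------------------------------------
# packaged profiles
# --------------------------------------------------------------------------

def ilvit_default_config(variant: str = "V4", num_classes: int = 4,
                         image_size: int = 224) -> ModelConfig:
    """The packaged full-size profile (see ``profiles/ilvit_default.yaml``
    for the calibration arithmetic behind the ODC/KAN settings)."""
    return ModelConfig(variant=variant, num_classes=num_classes,
                       image_size=image_size)


def tiny_test_config(variant: str = "V4", num_classes: int = 4) -> ModelConfig:
    """A two-stage reduced geometry (32×32 input, widths 16/32) preserving
    every ladder substitution; used for training-sanity experiments."""
    return ModelConfig(
        variant=variant, num_classes=num_classes, image_size=32,
        stage_depths=(1, 1), embed_dims=(16, 32), stage_heads=(1, 2),
        dic=DICConfig(embed_dim=16, branch_ratios=(0.25, 0.25, 0.25, 0.25)),
        odc_group_width=8, kv_res_ceiling=4)
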