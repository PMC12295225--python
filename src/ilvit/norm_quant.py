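"""Contrastive normalization and quantization primitives.

* :class:`ContraNorm` disperses token representations to counter
  dimensional collapse: ``x ← (1+s)·x − s·softmax(x xᵀ)·x`` followed by
  layer normalization; with ``s = 0`` it is exactly layer normalization.
* Uniform affine quantization (8-bit default) for the final linear layer,
  applied as fake-quant in the forward pass so gradients flow through a
  straight-through estimator.
* Log2 quantization for post-softmax activations (codes are rounded
  negative base-2 logarithms) together with a second-order polynomial
  approximation of the exponential, the integer-friendly softmax recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tensor import Parameter, Tensor

__all__ = [
    "ContraNormConfig", "ContraNorm", "contranorm",
    "QuantParams", "quantize_uniform", "dequantize_uniform",
    "log2_quantize", "log2_dequantize",
    "poly_exp", "poly_softmax",
    "QAct", "QuantLinear", "fake_quant",
]


# --------------------------------------------------------------------------
# contrastive normalization
# --------------------------------------------------------------------------

@dataclass
class ContraNormConfig:
    scale: float = 0.1       # dispersal strength s (s = 0 → plain layer norm)
    affine: bool = True

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


class ContraNorm(nn.Module):
    def __init__(self, dim: int, cfg: ContraNormConfig | None = None):
        super().__init__()
        self.cfg = cfg or ContraNormConfig()
        self.ln = nn.LayerNorm(dim, affine=self.cfg.affine)

    def forward(self, x: Tensor) -> Tensor:
        return contranorm(x, self)


def contranorm(x: Tensor, norm: ContraNorm) -> Tensor:
    """Dispersal update then layer normalization over the feature axis.

    ``x`` is ``(..., L, D)``; the token-similarity softmax is row-wise over
    the L×L Gram matrix of each sample.
    """
    s = norm.cfg.scale
    if s > 0:
        sim = x @ x.swapaxes(-1, -2)            # (..., L, L)
        attn = sim.softmax(axis=-1)
        x = (1.0 + s) * x - s * (attn @ x)
    return norm.ln(x)


# --------------------------------------------------------------------------
# uniform quantization
# --------------------------------------------------------------------------

@dataclass
class QuantParams:
    """Uniform (scale / zero-point) or log2 (exponent range) quantizer state."""

    bit_width: int = 8
    mode: str = "uniform"          # "uniform" | "log2"
    scale: float = 1.0
    zero_point: int = 0
    min_val: float = 0.0           # observed calibration range
    max_val: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.mode not in ("uniform", "log2"):
            raise ValueError(f"unknown quantization mode {self.mode!r}")

    @property
    def n_levels(self) -> int:
        return 2 ** self.bit_width

    @classmethod
    def from_minmax(cls, min_val: float, max_val: float, bit_width: int = 8) -> "QuantParams":
        if max_val <= min_val:
            max_val = min_val + 1e-8
        scale = (max_val - min_val) / (2 ** bit_width - 1)
        zero_point = int(np.clip(round(-min_val / scale), 0, 2 ** bit_width - 1))
        return cls(bit_width=bit_width, scale=scale, zero_point=zero_point,
                   min_val=min_val, max_val=max_val)

    def to_dict(self) -> dict:
        return {"bit_width": self.bit_width, "mode": self.mode, "scale": self.scale,
                "zero_point": self.zero_point, "min_val": self.min_val,
                "max_val": self.max_val}


def quantize_uniform(x, qp: QuantParams) -> np.ndarray:
    """Integer codes ``clamp(round(x/scale) + zero_point, 0, 2^b − 1)``."""
    x = np.asarray(x, dtype=np.float64)
    codes = np.round(x / qp.scale) + qp.zero_point
    return np.clip(codes, 0, qp.n_levels - 1).astype(np.int64)


def dequantize_uniform(codes, qp: QuantParams) -> np.ndarray:
    return (np.asarray(codes, dtype=np.float64) - qp.zero_point) * qp.scale


def log2_quantize(p, bit_width: int = 8) -> np.ndarray:
    """Exponent codes ``clamp(round(−log2 p), 0, 2^b − 1)`` for p ∈ (0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0):
        raise ValueError("log2 quantization requires strictly positive inputs")
    codes = np.round(-np.log2(p))
    return np.clip(codes, 0, 2 ** bit_width - 1).astype(np.int64)


def log2_dequantize(codes) -> np.ndarray:
    return np.power(2.0, -np.asarray(codes, dtype=np.float64))


# --------------------------------------------------------------------------
# polynomial exponential / integer-friendly softmax
# --------------------------------------------------------------------------

_LN2 = float(np.log(2.0))
# second-order fit of e^x on [-ln2, 0]: a (x + b)^2 + c
_POLY_A, _POLY_B, _POLY_C = 0.3585, 1.353, 0.344


def poly_exp(x) -> np.ndarray:
    """Approximate ``e^x`` for x ≤ 0 via range reduction e^x = 2^-z · e^r.

    The residual r ∈ (−ln 2, 0] is evaluated with a fixed second-order
    polynomial; the relative error stays below 1% over the reduced range.
    """
    x = np.minimum(np.asarray(x, dtype=np.float64), 0.0)
    z = np.floor(-x / _LN2)
    r = x + z * _LN2                       # in (-ln2, 0]
    p = _POLY_A * (r + _POLY_B) ** 2 + _POLY_C
    return p * np.power(2.0, -z)


def poly_softmax(logits, axis: int = -1, bit_width: int | None = None) -> np.ndarray:
    """Softmax built from :func:`poly_exp`; optionally log2-quantized.

    With ``bit_width`` set, the normalized probabilities are rounded onto
    the 2^-code exponent grid (post-softmax log2 quantization).
    """
    logits = np.asarray(logits, dtype=np.float64)
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = poly_exp(shifted)
    p = e / e.sum(axis=axis, keepdims=True)
    if bit_width is not None:
        p = log2_dequantize(log2_quantize(np.maximum(p, 2.0 ** -(2 ** bit_width - 1)),
                                          bit_width))
    return p


# --------------------------------------------------------------------------
# fake-quant layers (straight-through estimator)
# --------------------------------------------------------------------------

def fake_quant(x: Tensor, qp: QuantParams) -> Tensor:
    """Quantize→dequantize in the forward pass; identity gradient."""
    y = dequantize_uniform(quantize_uniform(x.data, qp), qp)
    out = Tensor._make(y, (x,), None)
    out._backward = (lambda g: x._accum(g)) if out.requires_grad else None
    return out


class QAct(nn.Module):
    """Quantized activation: running min/max observer + uniform fake-quant.

    Calibration is per-batch in training mode (exponential running range);
    in eval mode the frozen range is used.
    """

    def __init__(self, bit_width: int = 8, momentum: float = 0.9):
        super().__init__()
        self.bit_width = bit_width
        self.momentum = momentum
        self.min_val = None
        self.max_val = None

    def observe(self, x: np.ndarray):
        lo, hi = float(x.min()), float(x.max())
        if self.min_val is None:
            self.min_val, self.max_val = lo, hi
        else:
            m = self.momentum
            self.min_val = m * self.min_val + (1 - m) * lo
            self.max_val = m * self.max_val + (1 - m) * hi

    def quant_params(self) -> QuantParams:
        return QuantParams.from_minmax(self.min_val, self.max_val, self.bit_width)

    def forward(self, x: Tensor) -> Tensor:
        if self.training or self.min_val is None:
            self.observe(x.data)
        return fake_quant(x, self.quant_params())


class QuantLinear(nn.Module):
    """Affine map with uniformly quantized weights (fake-quant, 8-bit default)."""

    def __init__(self, in_features: int, out_features: int, rng, bit_width: int = 8,
                 bias: bool = True):
        super().__init__()
        self.inner = nn.Linear(in_features, out_features, rng, bias=bias)
        self.bit_width = bit_width

    def forward(self, x: Tensor) -> Tensor:
        w = self.inner.weight
        qp = QuantParams.from_minmax(float(w.data.min()), float(w.data.max()),
                                     self.bit_width)
        wq = fake_quant(w, qp)
        y = x @ wq
        if self.inner.bias is not None:
            y = y + self.inner.bias
        return y
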