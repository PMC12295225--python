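"""Kolmogorov–Arnold network layers.

Instead of scalar weights, every edge of a KAN layer carries a trainable
univariate function: a B-spline expansion on a fixed grid plus a smooth
base gate,

    φ_ij(x) = w_b[ij] · silu(x) + w_s[ij] · Σ_m c_ijm B_m(x),
    out_j   = Σ_i φ_ij(x_i).

The spline basis follows the Cox–de Boor recursion on a uniform knot
vector over ``grid_range``; inputs outside the grid are handled by linear
extrapolation from the boundary, and the grid is static so evaluation is
deterministic.  :class:`ChannelKAN` is the diagonal special case — one
univariate spline per channel, no mixing — used where a near
parameter-free nonlinear stage is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Parameter, Tensor

__all__ = ["KANLayerConfig", "bspline_basis", "KANLayer", "ChannelKAN", "KANMixer"]


@dataclass
class KANLayerConfig:
    in_dim: int = 16
    out_dim: int = 16
    grid_size: int = 5        # G intervals on grid_range
    spline_order: int = 3     # k (cubic default)
    grid_range: tuple = (-1.0, 1.0)
    base_activation: str = "silu"

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.spline_order

    def knots(self) -> np.ndarray:
        lo, hi = self.grid_range
        g, k = self.grid_size, self.spline_order
        h = (hi - lo) / g
        return lo + np.arange(-k, g + k + 1) * h


def bspline_basis(t, grid, order: int) -> np.ndarray:
    """Cox–de Boor B-spline basis values, shape ``t.shape + (n_basis,)``.

    ``grid`` is the full (strictly increasing) knot vector; ``n_basis`` is
    ``len(grid) - 1 - order``.  Degree 0 gives the half-open interval
    indicators.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("knot vector must be strictly increasing")
    b, _ = _basis_and_deriv(np.asarray(t, dtype=np.float64), grid, order)
    return b


def _basis_and_deriv(t: np.ndarray, knots: np.ndarray, k: int):
    """Basis values and their first derivatives at points ``t`` (flat-safe)."""
    shape = t.shape
    t = t.reshape(-1, 1)
    b = ((t >= knots[:-1]) & (t < knots[1:])).astype(np.float64)
    prev = b
    for d in range(1, k + 1):
        prev = b
        left = (t - knots[: -d - 1]) / (knots[d:-1] - knots[: -d - 1]) * b[:, :-1]
        right = (knots[d + 1:] - t) / (knots[d + 1:] - knots[1:-d]) * b[:, 1:]
        b = left + right
    if k == 0:
        deriv = np.zeros_like(b)
    else:
        w1 = k / (knots[k:-1] - knots[:-k - 1])
        w2 = k / (knots[k + 1:] - knots[1:-k])
        deriv = w1 * prev[:, :-1] - w2 * prev[:, 1:]
    n_basis = len(knots) - 1 - k
    return b.reshape(shape + (n_basis,)), deriv.reshape(shape + (n_basis,))


def _basis_tensor(x: Tensor, cfg: KANLayerConfig) -> Tensor:
    """Autograd-aware basis evaluation with linear boundary extrapolation."""
    knots = cfg.knots()
    lo, hi = cfg.grid_range
    eps = 1e-9 * (hi - lo)
    tc = np.clip(x.data, lo, hi - eps)
    b, db = _basis_and_deriv(tc, knots, cfg.spline_order)
    delta = (x.data - tc)[..., None]
    value = b + delta * db                    # linear extension outside the grid
    out = Tensor._make(value, (x,), None)

    def bwd(g):
        x._accum((g * db).sum(axis=-1))

    out._backward = bwd if out.requires_grad else None
    return out


class KANLayer(nn.Module):
    """Full edge-grid KAN layer: ``in_dim · out_dim`` univariate splines.

    Parameters: ``in·out·(G+k)`` spline coefficients, plus per-edge base
    and scale weights and an output bias.
    """

    def __init__(self, cfg: KANLayerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        m = cfg.n_basis
        self.spline_coef = Parameter(rng.normal(0.0, 0.1, size=(cfg.in_dim, cfg.out_dim, m)))
        self.spline_scale = Parameter(np.ones((cfg.in_dim, cfg.out_dim)))
        self.base_weight = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(cfg.in_dim), size=(cfg.in_dim, cfg.out_dim)))
        self.bias = Parameter(np.zeros(cfg.out_dim))

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        lead = x.shape[:-1]
        xf = x.reshape((-1, cfg.in_dim))
        basis = _basis_tensor(xf, cfg)                       # (N, in, M)
        coef = (self.spline_coef * self.spline_scale.reshape(
            cfg.in_dim, cfg.out_dim, 1))
        cmat = coef.swapaxes(1, 2).reshape((cfg.in_dim * cfg.n_basis, cfg.out_dim))
        spline = basis.reshape((-1, cfg.in_dim * cfg.n_basis)) @ cmat
        base = xf.silu() @ self.base_weight
        y = spline + base + self.bias
        return y.reshape(lead + (cfg.out_dim,))


class ChannelKAN(nn.Module):
    """Diagonal KAN: one trainable univariate spline per channel.

    ``out_i = w_b[i]·silu(x_i) + w_s[i]·Σ_m c_im B_m(x_i)`` — a learnable
    spline activation layer costing ``(G + k) + 2`` parameters per channel.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 grid_size: int = 5, spline_order: int = 3,
                 grid_range=(-1.0, 1.0)):
        super().__init__()
        self.cfg = KANLayerConfig(in_dim=dim, out_dim=dim, grid_size=grid_size,
                                  spline_order=spline_order, grid_range=tuple(grid_range))
        self.spline_coef = Parameter(rng.normal(0.0, 0.1, size=(dim, self.cfg.n_basis)))
        self.spline_scale = Parameter(np.ones(dim))
        self.base_weight = Parameter(np.ones(dim))

    def forward(self, x: Tensor) -> Tensor:
        basis = _basis_tensor(x, self.cfg)                   # (..., dim, M)
        coef = self.spline_coef * self.spline_scale.reshape(-1, 1)
        spline = (basis * coef).sum(axis=-1)
        return self.base_weight * x.silu() + spline


class KANMixer(nn.Module):
    """Token-wise KAN feed-forward stage for a transformer block.

    ``mode``:
      * ``"full"`` — single full-edge KAN layer dim→dim (the layer default);
      * ``"bottleneck"`` — KAN dim→width then width→dim;
      * ``"channelwise"`` — diagonal spline activation (near parameter-free).
    """

    def __init__(self, dim: int, rng: np.random.Generator, mode: str = "full",
                 width: int | None = None, grid_size: int = 5, spline_order: int = 3,
                 grid_range=(-1.0, 1.0)):
        super().__init__()
        self.mode = mode
        kw = dict(grid_size=grid_size, spline_order=spline_order,
                  grid_range=tuple(grid_range))
        if mode == "full":
            self.layers = nn.ModuleList([
                KANLayer(KANLayerConfig(in_dim=dim, out_dim=dim, **kw), rng)])
        elif mode == "bottleneck":
            if width is None:
                raise ValueError("bottleneck KAN requires a width")
            self.layers = nn.ModuleList([
                KANLayer(KANLayerConfig(in_dim=dim, out_dim=width, **kw), rng),
                KANLayer(KANLayerConfig(in_dim=width, out_dim=dim, **kw), rng)])
        elif mode == "channelwise":
            self.layers = nn.ModuleList([ChannelKAN(dim, rng, **kw)])
        else:
            raise ValueError(f"unknown KAN mode {mode!r}")

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
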