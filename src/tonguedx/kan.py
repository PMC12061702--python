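"""Kolmogorov-Arnold classifier layers.

In a KAN layer every edge (i → j) carries a learnable univariate function
φ_{j,i} instead of a scalar weight, and each output unit is the plain sum
x_{l+1,j} = Σ_i φ_{l,j,i}(x_{l,i}); a network is the composition of such
layers. Here each edge function is a cubic B-spline on a fixed grid plus a
SiLU residual term, φ(x) = w_base·silu(x) + Σ_m c_m B_m(x), with linear
extrapolation outside the grid. Spline coefficients start near zero so an
untrained layer behaves like a (He-initialised) SiLU-gated linear map.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module, he_init

__all__ = ["KanEdge", "KANLayer", "KAN"]


class KANLayer(Module):
    """One KAN layer: n_in → n_out with a spline+SiLU function on every edge."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 grid_range: tuple = (-2.0, 2.0), n_intervals: int = 8,
                 order: int = 3, coeff_scale: float = 0.01):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.grid = np.linspace(grid_range[0], grid_range[1], n_intervals + 1)
        self.order = order
        n_basis = n_intervals + order
        self.coeffs = Tensor(
            rng.normal(0.0, coeff_scale, size=(n_out, n_in, n_basis)), requires_grad=True
        )
        self.base_weight = Tensor(he_init(rng, (n_out, n_in), n_in), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim == 1:
            x = x.reshape(1, x.shape[0])
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} inputs, got {x.shape[1]}")
        spline = ad.kan_spline(x, self.coeffs, self.grid, self.order)
        base = ad.silu(x) @ self.base_weight.transpose(1, 0)
        return spline + base


class KanEdge:
    """A single learnable univariate edge function φ (a 1→1 KAN layer view).

    φ(x) = base_weight·silu(x) + Σ_m spline_coeffs[m]·B_m(x), with linear
    extrapolation outside the knot grid.
    """

    def __init__(self, spline_coeffs: np.ndarray, grid: np.ndarray, order: int = 3,
                 base_weight: float = 0.0):
        grid = np.asarray(grid, dtype=np.float64)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid knots must be strictly increasing")
        n_basis = len(grid) + order - 1
        spline_coeffs = np.asarray(spline_coeffs, dtype=np.float64)
        if spline_coeffs.shape != (n_basis,):
            raise ValueError(f"expected {n_basis} coefficients (knots+order-1), "
                             f"got {spline_coeffs.shape}")
        self.spline_coeffs, self.grid, self.order = spline_coeffs, grid, order
        self.base_weight = float(base_weight)

    def __call__(self, x) -> np.ndarray | float:
        xs = np.asarray(x, dtype=np.float64)
        xc = np.clip(xs, self.grid[0], self.grid[-1])
        B, dB = ad.bspline_basis(xc, self.grid, self.order)
        val = (B + dB * (xs - xc)[..., None]) @ self.spline_coeffs
        s = xs / (1.0 + np.exp(-xs))
        out = self.base_weight * s + val
        return float(out) if np.isscalar(x) or np.asarray(x).ndim == 0 else out

    @staticmethod
    def fit(target_fn, grid: np.ndarray, order: int = 3, n_fit: int = 512) -> "KanEdge":
        """Least-squares spline fit of a univariate function on the grid."""
        grid = np.asarray(grid, dtype=np.float64)
        xs = np.linspace(grid[0], grid[-1], n_fit)
        B, _ = ad.bspline_basis(xs, grid, order)
        coeffs, *_ = np.linalg.lstsq(B, np.asarray([target_fn(v) for v in xs]), rcond=None)
        return KanEdge(coeffs, grid, order=order, base_weight=0.0)


class KAN(Module):
    """Composition of KAN layers: KAN(x) = Φ_{L−1} ∘ … ∘ Φ_0 (x)."""

    def __init__(self, widths: list[int], rng: np.random.Generator, **layer_kwargs):
        super().__init__()
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.layers = [
            KANLayer(widths[i], widths[i + 1], rng, **layer_kwargs)
            for i in range(len(widths) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
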