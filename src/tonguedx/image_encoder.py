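"""Hierarchical aggregation image encoder.

The tongue image is mapped to an embedding in three stages:

1. a 1×1 convolutional stem projects RGB pixels into a hidden channel space
   (Z⁰),
2. a chain of grouped convolutions extracts features at increasing receptive
   fields (Z¹ … Z^N), with a closed-form recursion
   ``l(N) = l(N−1) + (k(N)−1)·∏_{i<N} s(i)`` giving the receptive field per
   level, and a global average pooling of the last level supplies a global
   context map Z^{N+1},
3. a gated aggregation network scores every level at every pixel
   (softmax-normalised over levels) and sums the gated levels into one map,
   which is average-pooled and projected to the embedding vector.

Coarser levels are bilinearly resampled to the finest retained grid (the
stem's grid) before gating, so the per-pixel mixture is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Linear, Module

__all__ = ["LayerSpec", "receptive_field", "HANEncoder", "global_context"]


@dataclass(frozen=True)
class LayerSpec:
    """One grouped-convolution level: kernel size, stride, groups, width."""

    kernel: int
    stride: int
    groups: int
    out_channels: int

    def __post_init__(self):
        if self.kernel <= 0 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd positive, got {self.kernel}")
        if self.stride <= 0:
            raise ValueError(f"stride must be positive, got {self.stride}")
        if self.out_channels % self.groups:
            raise ValueError(
                f"out_channels={self.out_channels} not divisible by groups={self.groups}"
            )


def receptive_field(specs: list[LayerSpec], l0: int = 1) -> list[int]:
    """Receptive field sizes l(1) … l(N) for a chain of conv levels.

    Follows the recursion l(N) = l(N−1) + (k(N)−1)·∏_{i=1}^{N−1} s(i),
    with l(0) = l0.
    """
    if l0 < 1:
        raise ValueError(f"l0 must be >= 1, got {l0}")
    out, l, jump = [], l0, 1
    for spec in specs:
        l = l + (spec.kernel - 1) * jump
        out.append(l)
        jump *= spec.stride
    return out


def global_context(z: Tensor) -> Tensor:
    """Per-channel spatial mean of a (B,C,H,W) map, broadcast back to H×W."""
    g = z.mean(axis=(2, 3), keepdims=True)
    ones = Tensor(np.ones((1, 1) + z.shape[2:]))
    return g * ones


def _default_specs(hidden: int, n_levels: int, groups: int, strides=None) -> list[LayerSpec]:
    if strides is None:
        strides = [2, 2] + [1] * (n_levels - 2) if n_levels >= 2 else [1] * n_levels
    return [LayerSpec(3, int(s), groups, hidden) for s in strides[:n_levels]]


class HANEncoder(Module):
    """Hierarchical encoder + gated aggregation producing the image embedding.

    All levels share ``hidden_channels`` so the gated sum is well typed; the
    gate network is a 1×1 convolution over the channel-concatenated levels
    with one output plane per aggregated level (Z¹…Z^{N+1}).
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 3,
                 hidden_channels: int = 64, n_levels: int = 4, groups: int = 4,
                 embed_dim: int = 128, specs: list[LayerSpec] | None = None):
        super().__init__()
        if hidden_channels <= 0:
            raise ValueError(f"hidden_channels must be positive, got {hidden_channels}")
        if specs is None:
            specs = _default_specs(hidden_channels, n_levels, groups)
        for s in specs:
            if s.out_channels != hidden_channels:
                raise ValueError("all levels must share hidden_channels for aggregation")
        self.specs = specs
        self.stem = Conv2d(in_channels, hidden_channels, 1, rng)
        self.convs = [
            Conv2d(hidden_channels, s.out_channels, s.kernel, rng, stride=s.stride,
                   padding=s.kernel // 2, groups=s.groups)
            for s in specs
        ]
        n_agg = len(specs) + 1  # Z¹…Z^N plus the global-context level
        self.gate = Conv2d(hidden_channels * (len(specs) + 2), n_agg, 1, rng)
        self.proj = Linear(hidden_channels, embed_dim, rng)
        self.embed_dim = embed_dim

    # ---- stage operations (exposed for direct testing) -------------------
    def stem_project(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.stem.weight.shape[1]:
            raise ValueError(f"expected (B,{self.stem.weight.shape[1]},H,W), got {x.shape}")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError(f"image must be at least 32x32, got {x.shape[2:]}")
        return self.stem(x)

    def hierarchical_encode(self, z0: Tensor) -> list[Tensor]:
        """Grouped-conv chain with GELU after each level; returns Z¹…Z^N."""
        zs, z = [], z0
        for conv in self.convs:
            z = ad.gelu(conv(z))
            zs.append(z)
        return zs

    def receptive_field(self, l0: int = 1) -> list[int]:
        return receptive_field(self.specs, l0)

    @staticmethod
    def _to_common(levels: list[Tensor]) -> list[Tensor]:
        # The gated sum runs over Z¹…Z^{N+1}, so the common grid is the finest
        # grid among those levels (Z¹'s); Z⁰ is resampled onto it for the gate.
        grid = max((z.shape[2], z.shape[3]) for z in levels[1:])
        return [ad.upsample_bilinear(z, grid) for z in levels]

    def gated_aggregate(self, levels: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Softmax-gated sum over Z¹…Z^{N+1}; gate sees all levels incl. Z⁰.

        `levels` is the full list [Z⁰, Z¹, …, Z^{N+1}] on a common grid.
        Returns (aggregated map, gates); gates sum to 1 over the level axis.
        """
        grids = {(z.shape[2], z.shape[3]) for z in levels}
        if len(grids) != 1:
            raise ValueError(f"levels not on a common grid: {sorted(grids)}")
        gates = ad.softmax(self.gate(ad.concatenate(levels, axis=1)), axis=1)
        agg = None
        for j, z in enumerate(levels[1:]):  # aggregate Z¹…Z^{N+1}
            term = gates[:, j : j + 1] * z
            agg = term if agg is None else agg + term
        return agg, gates

    # ---- full encoder ----------------------------------------------------
    def __call__(self, x: Tensor) -> Tensor:
        z0 = self.stem_project(x)
        hier = self.hierarchical_encode(z0)
        levels = self._to_common([z0] + hier + [global_context(hier[-1])])
        agg, _ = self.gated_aggregate(levels)
        pooled = agg.mean(axis=(2, 3))
        return self.proj(pooled)
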