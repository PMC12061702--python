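"""Cross-modal fusion: bridging, three-subspace projection, EMA attention.

The image and text embeddings are concatenated and passed through a linear
bridge to the fused feature F, which is projected by three independent
affine maps into subspaces F₁, F₂, F₃ carrying complementary views. Each
subspace vector is reshaped into a small grouped spatial tile so that a
multi-scale channel attention (EMA: height-wise, width-wise, and global
average poolings feeding two parallel branches with cross-dimensional
interaction) can reweight it; the three reweighted subspaces are summed and
layer-normalised into the classifier input F′.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Dropout, LayerNorm, Linear, Module

__all__ = [
    "ema_pool_height",
    "ema_pool_width",
    "ema_pool_global",
    "EMAAttention",
    "FusionModule",
]


def _wrap(x):
    return (x, True) if isinstance(x, Tensor) else (Tensor(np.asarray(x, dtype=np.float64)), False)


def _unwrap(t, was):
    return t if was else t.data


def ema_pool_height(x):
    """Mean over the width axis at each height: z_c^H(h) = (1/W) Σ_i x_c(h,i)."""
    t, was = _wrap(x)
    return _unwrap(t.mean(axis=-1), was)


def ema_pool_width(x):
    """Mean over the height axis at each width: z_c^W(w) = (1/H) Σ_j x_c(j,w)."""
    t, was = _wrap(x)
    return _unwrap(t.mean(axis=-2), was)


def ema_pool_global(x):
    """Global spatial mean per channel: z_c = (1/HW) Σ_j Σ_i x_c(j,i)."""
    t, was = _wrap(x)
    return _unwrap(t.mean(axis=(-2, -1)), was)


class EMAAttention(Module):
    """Multi-scale attention over a grouped feature map (B*, C, H, W).

    Branch 1 (1×1): the height and width pooling profiles are concatenated,
    passed through a shared 1×1 transform, split back, and sigmoid-gated onto
    the input. Branch 2 (3×3): a 3×3 convolution of the input. Cross
    interaction: the softmax of each branch's global pooling is matrix-
    multiplied against the other branch's flattened spatial map; the sum of
    the two products passes a final sigmoid gate that reweights the input.
    Output shape equals input shape; all gate activations lie in (0, 1).
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv1 = Conv2d(channels, channels, 1, rng)
        self.conv3 = Conv2d(channels, channels, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        zh = ema_pool_height(x)  # (B,C,H)
        zw = ema_pool_width(x)  # (B,C,W)
        prof = ad.concatenate([zh, zw], axis=2).reshape(B, C, H + W, 1)
        t = self.conv1(prof)
        th = t[:, :, :H].reshape(B, C, H, 1)
        tw = t[:, :, H:].reshape(B, C, 1, W)
        x1 = x * ad.sigmoid(th) * ad.sigmoid(tw)
        x2 = self.conv3(x)
        g1 = ad.softmax(ema_pool_global(x1), axis=1).reshape(B, 1, C)
        g2 = ad.softmax(ema_pool_global(x2), axis=1).reshape(B, 1, C)
        a = g1 @ x2.reshape(B, C, H * W)
        b = g2 @ x1.reshape(B, C, H * W)
        gate = ad.sigmoid((a + b).reshape(B, 1, H, W))
        return x * gate


class FusionModule(Module):
    """bridge → subspaces → per-subspace EMA → recombine.

    The fused dimension d_f must factor as groups · channels · tile²; each
    subspace vector is viewed as (B·groups, channels, tile, tile) for EMA.
    """

    def __init__(self, rng: np.random.Generator, embed_dim: int = 128,
                 d_f: int = 256, groups: int = 4, tile: int = 4,
                 dropout: float = 0.5):
        super().__init__()
        if d_f % (groups * tile * tile):
            raise ValueError(f"d_f={d_f} must be divisible by groups*tile²={groups * tile * tile}")
        self.d_f, self.groups, self.tile = d_f, groups, tile
        self.channels = d_f // (groups * tile * tile)
        self.bridge_fc = Linear(2 * embed_dim, d_f, rng)
        self.drop = Dropout(dropout, rng)
        self.proj1 = Linear(d_f, d_f, rng)
        self.proj2 = Linear(d_f, d_f, rng)
        self.proj3 = Linear(d_f, d_f, rng)
        # three parallel, unshared attention blocks — one per subspace branch
        self.emas = [EMAAttention(self.channels, rng) for _ in range(3)]
        self.norm = LayerNorm(d_f)

    def bridge(self, zt: Tensor, zs: Tensor) -> Tensor:
        """Concatenate the two modality embeddings, linear map + GELU."""
        if zt.shape[-1] != zs.shape[-1]:
            raise ValueError(f"dimension mismatch: {zt.shape[-1]} vs {zs.shape[-1]}")
        return self.drop(ad.gelu(self.bridge_fc(ad.concatenate([zt, zs], axis=-1))))

    def project_subspaces(self, f: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """The three affine projections F_i = W_i F + b_i."""
        return self.proj1(f), self.proj2(f), self.proj3(f)

    def _to_tile(self, f: Tensor) -> Tensor:
        B = f.shape[0]
        return f.reshape(B * self.groups, self.channels, self.tile, self.tile)

    def _from_tile(self, x: Tensor, batch: int) -> Tensor:
        return x.reshape(batch, self.d_f)

    def recombine(self, f1w: Tensor, f2w: Tensor, f3w: Tensor) -> Tensor:
        """Element-wise sum of the weighted subspaces, then layer norm."""
        return self.norm(f1w + f2w + f3w)

    def __call__(self, zt: Tensor, zs: Tensor) -> Tensor:
        f = self.bridge(zt, zs)
        B = f.shape[0]
        weighted = []
        for proj, ema in zip(self.project_subspaces(f), self.emas):
            weighted.append(self._from_tile(ema(self._to_tile(proj)), B))
        return self.recombine(*weighted)
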