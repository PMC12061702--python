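"""The assembled multimodal multi-label classifier.

Image → hierarchical gated encoder → Z_t; text record → attribute encoder →
Z_s (both d-dimensional, Euclidean). The two embeddings are fused
(bridge → three subspaces → EMA attention → recombined F′) and F′ feeds two
stacked-KAN heads sharing the trunk: one for the 10 pathology labels, one
for the 9 location labels; sigmoid outputs give per-label probabilities.
For the dual-space losses the embeddings and the probability/target vectors
are carried into the Poincaré ball by the origin exponential map.

In unimodal modes the missing modality's embedding is replaced by zeros at
the bridge, and for the image-only path the text record is never read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fusion import FusionModule
from .image_encoder import HANEncoder, LayerSpec
from .kan import KAN
from .nn import Module
from .text_encoder import TextEncoder, TextSchema

__all__ = ["ModelConfig", "TongueClassifier"]

N_PATHOLOGY, N_LOCATION = 10, 9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture dimensions (the reference scale; tests use smaller ones)."""

    hidden_channels: int = 64
    n_levels: int = 4
    conv_groups: int = 4
    embed_dim: int = 128
    d_f: int = 256
    ema_groups: int = 4
    ema_tile: int = 4
    kan_hidden: int = 64
    attr_dim: int = 8
    text_hidden: int = 64
    dropout: float = 0.5
    strides: tuple | None = None

    def small(self) -> "ModelConfig":
        """A compact configuration for CPU-scale experiments."""
        return ModelConfig(hidden_channels=16, n_levels=3, conv_groups=4,
                           embed_dim=64, d_f=256, ema_groups=4, ema_tile=4,
                           kan_hidden=32, attr_dim=8, text_hidden=64,
                           dropout=self.dropout, strides=(2, 2, 1))

    def smoke(self) -> "ModelConfig":
        """The configuration used for the learning smoke experiments."""
        return ModelConfig(hidden_channels=16, n_levels=3, conv_groups=4,
                           embed_dim=128, d_f=1024, ema_groups=4, ema_tile=4,
                           kan_hidden=64, attr_dim=8, text_hidden=128,
                           dropout=self.dropout, strides=(2, 2, 1))


class TongueClassifier(Module):
    """Shared trunk, two KAN heads; forward returns probabilities + embeddings."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 schema: TextSchema | None = None):
        super().__init__()
        self.cfg = cfg
        specs = None
        if cfg.strides is not None:
            specs = [LayerSpec(3, int(s), cfg.conv_groups, cfg.hidden_channels)
                     for s in cfg.strides]
        self.image_encoder = HANEncoder(
            rng, hidden_channels=cfg.hidden_channels, n_levels=cfg.n_levels,
            groups=cfg.conv_groups, embed_dim=cfg.embed_dim, specs=specs)
        self.text_encoder = TextEncoder(
            rng, schema=schema, attr_dim=cfg.attr_dim, hidden=cfg.text_hidden,
            embed_dim=cfg.embed_dim, dropout=cfg.dropout)
        self.fusion = FusionModule(
            rng, embed_dim=cfg.embed_dim, d_f=cfg.d_f, groups=cfg.ema_groups,
            tile=cfg.ema_tile, dropout=cfg.dropout)
        self.head_pathology = KAN([cfg.d_f, cfg.kan_hidden, N_PATHOLOGY], rng)
        self.head_location = KAN([cfg.d_f, cfg.kan_hidden, N_LOCATION], rng)

    def __call__(self, images: np.ndarray | None, text_idx: np.ndarray | None,
                 modality: str = "both") -> dict:
        if modality not in ("both", "image", "text"):
            raise ValueError(f"modality must be both/image/text, got {modality!r}")
        if modality in ("both", "image"):
            zt = self.image_encoder(ad.as_tensor(images))
            batch = zt.shape[0]
        else:
            zt = None
        if modality in ("both", "text"):
            zs = self.text_encoder(text_idx)
            batch = zs.shape[0]
        else:
            zs = None
        zeros = Tensor(np.zeros((batch, self.cfg.embed_dim)))
        fused = self.fusion(zt if zt is not None else zeros,
                            zs if zs is not None else zeros)
        out = {
            "z_image": zt,
            "z_text": zs,
            "fused": fused,
            "prob_pathology": ad.sigmoid(self.head_pathology(fused)),
            "prob_location": ad.sigmoid(self.head_location(fused)),
        }
        return out
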