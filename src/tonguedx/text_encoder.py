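"""Structured tongue-description text encoder.

The text modality is an expert annotation record — categorical attributes
such as body colour, coating, moisture, teeth marks, cracks, and per-organ
indications — rather than free prose, matching how tongue datasets are
annotated in practice. Records are vectorised attribute-by-attribute against
a fixed schema (unknown values map to an explicit UNK token), embedded per
attribute, and passed through a two-layer perceptron with dropout to an
embedding the same width as the image embedding. An optional free-text field
is folded in as a hashed bag of tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Dropout, Embedding, Linear, Module

__all__ = ["TextRecord", "TextSchema", "TextEncoder", "DEFAULT_SCHEMA"]

UNK = "UNK"

# Pathology sign attributes (one clinical sign per syndrome family), shared
# stylistic attributes, and per-organ indication attributes.
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "body_color": ("pink", "red", "pale", "purple"),
    "coating_thickness": ("thin", "thick"),
    "moisture": ("normal", "moist", "dry"),
    "shape": ("normal", "swollen", "thin"),
    "teeth_marks": ("absent", "present"),
    "cracks": ("absent", "present"),
    "pale_blue_tinge": ("absent", "present"),
    "sublingual_vein_distension": ("absent", "present"),
    "yellow_coating": ("absent", "present"),
    "greasy_coating": ("absent", "present"),
    "thick_slippery_coating": ("absent", "present"),
    "pale_dry_body": ("absent", "present"),
    "ecchymosis_spots": ("absent", "present"),
    "swollen_moist_body": ("absent", "present"),
    "sign_intestine": ("absent", "present"),
    "sign_lung": ("absent", "present"),
    "sign_liver": ("absent", "present"),
    "sign_spleen": ("absent", "present"),
    "sign_kidney": ("absent", "present"),
    "sign_stomach": ("absent", "present"),
    "sign_heart": ("absent", "present"),
    "atypical_presentation": ("absent", "present"),
}


@dataclass
class TextRecord:
    attributes: dict[str, str]
    free_text: str | None = None


@dataclass
class TextSchema:
    """Fixed attribute ordering and vocabularies (each ends with UNK)."""

    attributes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMA)
    )

    def __post_init__(self):
        self._names = list(self.attributes)
        self._vocabs = {a: tuple(v) + (UNK,) for a, v in self.attributes.items()}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def vocab(self, attr: str) -> tuple[str, ...]:
        return self._vocabs[attr]

    def vectorize(self, rec: TextRecord) -> np.ndarray:
        """Deterministic one-index-per-attribute encoding; UNK for unseen values."""
        for a in rec.attributes:
            if a not in self._vocabs:
                raise KeyError(f"attribute {a!r} not in schema")
        idx = np.empty(len(self._names), dtype=np.int64)
        for i, a in enumerate(self._names):
            vocab = self._vocabs[a]
            val = rec.attributes.get(a, UNK)
            idx[i] = vocab.index(val) if val in vocab else len(vocab) - 1
        return idx

    def devectorize(self, idx: np.ndarray) -> TextRecord:
        attrs = {a: self._vocabs[a][int(idx[i])] for i, a in enumerate(self._names)}
        return TextRecord(attributes=attrs)


def hash_bag_of_tokens(text: str | None, n_buckets: int = 32) -> np.ndarray:
    """Stable hashed token counts for the optional free-text field."""
    vec = np.zeros(n_buckets)
    if not text:
        return vec
    for tok in text.lower().split():
        h = 0
        for ch in tok:  # small stable FNV-style hash (builtin hash is salted)
            h = (h * 131 + ord(ch)) % (2**31)
        vec[h % n_buckets] += 1.0
    return vec


class TextEncoder(Module):
    """Per-attribute embeddings → concat (+ hashed free text) → 2-layer MLP."""

    def __init__(self, rng: np.random.Generator, schema: TextSchema | None = None,
                 attr_dim: int = 8, hidden: int = 64, embed_dim: int = 128,
                 dropout: float = 0.5, n_text_buckets: int = 32):
        super().__init__()
        self.schema = schema or TextSchema()
        # Learnable per-attribute tables, initialised one-hot (the canonical
        # categorical encoding) so attribute identity is linearly readable
        # from the first step; values beyond attr_dim wrap around.
        self.tables = []
        for a in self.schema.names:
            table = Embedding(len(self.schema.vocab(a)), attr_dim, rng)
            w = np.zeros_like(table.weight.data)
            for v in range(w.shape[0]):
                w[v, v % attr_dim] = 1.0
            table.weight.data = w
            self.tables.append(table)
        n_in = attr_dim * len(self.schema.names) + n_text_buckets
        self.n_text_buckets = n_text_buckets
        self.fc1 = Linear(n_in, hidden, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(hidden, embed_dim, rng)
        self.embed_dim = embed_dim

    def __call__(self, idx: np.ndarray, bags: np.ndarray | None = None) -> Tensor:
        """idx: (B, n_attrs) int matrix; bags: optional (B, n_buckets)."""
        idx = np.atleast_2d(np.asarray(idx))
        if idx.shape[1] != len(self.tables):
            raise ValueError(f"expected {len(self.tables)} attribute indices, got {idx.shape[1]}")
        parts = [table(idx[:, i]) for i, table in enumerate(self.tables)]
        if bags is None:
            bags = np.zeros((idx.shape[0], self.n_text_buckets))
        parts.append(Tensor(np.asarray(bags, dtype=np.float64)))
        h = ad.gelu(self.fc1(ad.concatenate(parts, axis=1)))
        return self.fc2(self.drop(h))
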