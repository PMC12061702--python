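"""Consistency, cross-entropy, complementarity and total training losses.

The model is trained in two representation spaces at once:

* ``L_ce`` — mean binary cross-entropy between predicted per-label
  probabilities and the binary targets (the Euclidean prediction loss for a
  multi-label task).
* ``L_consis`` — compares the *batch vector* of per-sample image↔text
  distances measured in Euclidean space (squared norm, D_es) with the same
  vector measured in the Poincaré ball (D_hs): one minus their cosine. Zero
  iff the two distance profiles are positively proportional, i.e. the two
  spaces rank cross-modal similarity identically. A ``squared`` denominator
  variant (squared norms in the denominator, which is not scale-invariant)
  is kept behind a flag for fidelity experiments.
* ``L_compl`` — hyperbolic distance between the exponential-map images of
  the predicted and target label vectors, complementing the Euclidean BCE.
* ``L_total = w_ce·L_ce + w_consis·L_consis + w_compl·L_compl``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import Tensor

__all__ = [
    "LossWeights",
    "consistency_loss",
    "ce_loss",
    "complementarity_loss",
    "total_loss",
]

_PROB_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    w_ce: float = 1.0
    w_consis: float = 0.5
    w_compl: float = 0.5

    def __post_init__(self):
        if min(self.w_ce, self.w_consis, self.w_compl) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_ce == self.w_consis == self.w_compl == 0:
            raise ValueError("at least one loss weight must be positive")


def _wrap(x):
    return (x, True) if isinstance(x, Tensor) else (Tensor(np.asarray(x, dtype=np.float64)), False)


def _unwrap(t, was):
    return t if was else float(t.data)


def consistency_loss(d_es, d_hs, denominator: str = "plain"):
    """1 − cosine between the Euclidean and hyperbolic batch distance vectors.

    Both vectors must have the same length ≥ 2 and nonnegative entries. A
    zero-norm vector makes the cosine undefined; returns the neutral value 1
    with a warning. ``denominator='squared'`` uses squared norms instead
    (not scale-invariant; kept for fidelity experiments).
    """
    de, we = _wrap(d_es)
    dh, wh = _wrap(d_hs)
    if de.shape != dh.shape:
        raise ValueError(f"distance vectors differ in shape: {de.shape} vs {dh.shape}")
    if de.data.size < 2:
        raise ValueError("need at least 2 samples for the consistency loss")
    ne2 = (de**2.0).sum()
    nh2 = (dh**2.0).sum()
    if ne2.item() == 0.0 or nh2.item() == 0.0:
        warnings.warn("zero-norm distance vector; consistency loss undefined, returning 1",
                      stacklevel=2)
        return _unwrap(Tensor(1.0), we or wh)
    dot = (de * dh).sum()
    if denominator == "plain":
        den = ad.sqrt(ne2) * ad.sqrt(nh2)
    elif denominator == "squared":
        den = ne2 * nh2
    else:
        raise ValueError(f"denominator must be 'plain' or 'squared', got {denominator!r}")
    return _unwrap(1.0 - dot / den, we or wh)


def ce_loss(y_prob, y_true):
    """Mean binary cross-entropy over all labels and samples.

    Probabilities are clipped to [1e−7, 1−1e−7] before the logs.
    """
    yp, wp = _wrap(y_prob)
    yt, wt = _wrap(y_true)
    if yp.shape != yt.shape:
        raise ValueError(f"shape mismatch: {yp.shape} vs {yt.shape}")
    p = ad.clamp(yp, lo=_PROB_EPS, hi=1.0 - _PROB_EPS)
    nll = -(yt * ad.log(p) + (1.0 - yt) * ad.log(1.0 - p))
    return _unwrap(nll.mean(), wp or wt)


def complementarity_loss(y_hs, target_hs, c: float = 1.0):
    """Batch-mean Poincaré distance between mapped predictions and targets."""
    yp, wp = _wrap(y_hs)
    yt, wt = _wrap(target_hs)
    d = geometry.hyperbolic_distance(yp, yt, c=c)
    return _unwrap(d.mean() if d.ndim else d, wp or wt)


def total_loss(l_ce, l_consis, l_compl, weights: LossWeights):
    """Weighted sum of the three components."""
    return weights.w_ce * l_ce + weights.w_consis * l_consis + weights.w_compl * l_compl
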