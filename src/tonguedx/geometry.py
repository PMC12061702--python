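"""Euclidean and Poincaré-ball geometry shared by the loss functions.

The model scores feature agreement in two spaces at once: plain Euclidean
space, where the distance used is the *squared* L2 norm ``D_es(x,y) =
||x-y||²`` (kept squared deliberately — every consumer in this package is
written against that contract), and the Poincaré ball of curvature
magnitude ``c``, the open ball of radius 1/√c where

    d_c(x, y) = (1/√c) · arccosh(1 + 2c||x−y||² / ((1−c||x||²)(1−c||y||²)))

Euclidean feature vectors enter the ball through the exponential map at the
origin, ``exp0(v) = tanh(√c||v||)·v/(√c||v||)``, followed by a safety clip
that keeps points an ``eps`` margin inside the boundary.

All functions accept either numpy arrays or autodiff Tensors (the loss path
needs gradients); the last axis is the coordinate axis, leading axes are
batch axes. With plain arrays in, plain arrays (or floats) come out.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "euclidean_distance",
    "hyperbolic_distance",
    "exp_map_origin",
    "clip_to_ball",
    "ball_radius",
]

_U_FLOOR = 1e-30  # floor on the arccosh argument offset; keeps d(x,x)=0 to ~1e-15


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _unwrap(t: Tensor, any_tensor: bool):
    if any_tensor:
        return t
    return t.item() if t.data.ndim == 0 else t.data


def ball_radius(c: float) -> float:
    """Radius of the Poincaré ball with curvature magnitude ``c``."""
    if c <= 0:
        raise ValueError(f"curvature magnitude must be positive, got c={c}")
    return 1.0 / np.sqrt(c)


def _sqnorm(t: Tensor) -> Tensor:
    return (t**2.0).sum(axis=-1)


def euclidean_distance(x, y):
    """Squared Euclidean distance ``||x−y||²`` (the model's D_es; not a metric)."""
    xt, fx = _wrap(x)
    yt, fy = _wrap(y)
    if xt.shape[-1] != yt.shape[-1]:
        raise ValueError(f"dimension mismatch: {xt.shape[-1]} vs {yt.shape[-1]}")
    return _unwrap(_sqnorm(xt - yt), fx or fy)


def _check_in_ball(data: np.ndarray, c: float, name: str):
    norms = np.linalg.norm(np.atleast_2d(data), axis=-1)
    r = ball_radius(c)
    if np.any(norms >= r):
        raise ValueError(
            f"{name} lies on or outside the Poincaré ball (norm {norms.max():.6g} "
            f">= radius {r:.6g}); clip_to_ball first"
        )


def hyperbolic_distance(x, y, c: float = 1.0, validate: bool = True):
    """Poincaré-ball geodesic distance at curvature magnitude ``c``.

    Computed as (1/√c)·log(1 + u + √(u(u+2))) with
    u = 2c||x−y||²/((1−c||x||²)(1−c||y||²)), which equals arccosh(1+u) but is
    exact (0) on the diagonal. Points must be strictly inside the ball.
    """
    xt, fx = _wrap(x)
    yt, fy = _wrap(y)
    if xt.shape[-1] != yt.shape[-1]:
        raise ValueError(f"dimension mismatch: {xt.shape[-1]} vs {yt.shape[-1]}")
    if validate:
        _check_in_ball(xt.data, c, "x")
        _check_in_ball(yt.data, c, "y")
    num = 2.0 * c * _sqnorm(xt - yt)
    den = (1.0 - c * _sqnorm(xt)) * (1.0 - c * _sqnorm(yt))
    u = ad.clamp(num / den, lo=_U_FLOOR)
    d = ad.log(1.0 + u + ad.sqrt(u * (u + 2.0))) * (1.0 / np.sqrt(c))
    return _unwrap(d, fx or fy)


def clip_to_ball(x, c: float = 1.0, eps: float = 1e-5):
    """Rescale any vector with norm ≥ 1/√c − eps back to that norm.

    Interior points pass through unchanged (the zero vector included).
    """
    if not 0.0 < eps <= 1e-2:
        raise ValueError(f"eps must be in (0, 1e-2], got {eps}")
    xt, was = _wrap(x)
    max_norm = ball_radius(c) - eps
    norm = ad.sqrt(ad.clamp(_sqnorm(xt), lo=1e-30))
    scale = max_norm / ad.clamp(norm, lo=max_norm)
    out = xt * scale.reshape(scale.shape + (1,)) if xt.ndim > 1 else xt * scale
    return _unwrap(out, was)


def exp_map_origin(v, c: float = 1.0, eps: float = 1e-5):
    """Exponential map at the ball origin: tanh(√c||v||)·v/(√c||v||), then clip.

    Total on finite inputs; v=0 maps to 0; preserves direction and is
    monotone in ||v||. The final clip enforces the eps-interior invariant
    even where tanh saturates.
    """
    vt, was = _wrap(v)
    sc = np.sqrt(c)
    norm = ad.sqrt(ad.clamp(_sqnorm(vt), lo=1e-30))
    factor = ad.tanh(norm * sc) / (norm * sc)
    out = vt * factor.reshape(factor.shape + (1,)) if vt.ndim > 1 else vt * factor
    return _unwrap(clip_to_ball(out, c=c, eps=eps), was)
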