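"""Minimal reverse-mode automatic differentiation on numpy arrays.

All model components in this package are built on the :class:`Tensor` type
defined here: a numpy array plus a gradient buffer and a backward closure.
The op set is deliberately small — elementwise arithmetic, matmul, reductions,
shape ops, the activations the model uses, grouped 2-D convolution, bilinear
resampling, and a fused B-spline edge evaluation for the Kolmogorov-Arnold
layers. Everything is CPU-only numpy — float64 by default, float32 inside a
`default_dtype` context for the larger training runs — which keeps runs
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "tensor", "no_grad", "default_dtype"]

_GRAD_ENABLED = [True]
_DTYPE = [np.float64]


class default_dtype:
    """Context manager setting the dtype of newly created Tensors.

    Training at scale benefits from float32; the exact-value tests and the
    public geometry functions keep the float64 default.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        _DTYPE.append(self.dtype)
        return self

    def __exit__(self, *exc):
        _DTYPE.pop()
        return False


_PATH_CACHE: dict = {}


def _einsum(subs: str, *ops: np.ndarray) -> np.ndarray:
    """einsum with a cached contraction path (np.einsum re-plans per call)."""
    key = (subs,) + tuple(op.shape for op in ops)
    path = _PATH_CACHE.get(key)
    if path is None:
        path = np.einsum_path(subs, *ops, optimize="optimal")[0]
        _PATH_CACHE[key] = path
    return np.einsum(subs, *ops, optimize=path)


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _grad_on() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE[-1])
        self.requires_grad = requires_grad and _grad_on()
        self.grad = None
        self._backward = None
        self._parents = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_on() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        d = self.data

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * d ** (p - 1.0))

        return Tensor._make(d ** p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a, b), (self, other), bw)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(self.data.dtype))
            else:
                ge = np.expand_dims(g, axis) if not keepdims else g
                self._accum(np.broadcast_to(ge, self.shape).astype(self.data.dtype))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        return Tensor._make(self.data[idx], (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(x, requires_grad: bool = False) -> Tensor:
    return Tensor(x, requires_grad=requires_grad)


# ---- elementwise functions ----------------------------------------------

def _unary(x: Tensor, out_data, dfn) -> Tensor:
    def bw(g):
        if x.requires_grad:
            x._accum(g * dfn())

    return Tensor._make(out_data, (x,), bw)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    return _unary(x, e, lambda: e)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.log(x.data), lambda: 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sqrt(x.data)
    return _unary(x, s, lambda: 0.5 / s)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    return _unary(x, t, lambda: 1.0 - t * t)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, s, lambda: s * (1.0 - s))


def silu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, x.data * s, lambda: s * (1.0 + x.data * (1.0 - s)))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit, 0.5·x·(1+erf(x/√2))."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + _erf(x.data / np.sqrt(2.0)))
    pdf = np.exp(-0.5 * x.data**2) / np.sqrt(2.0 * np.pi)
    return _unary(x, x.data * phi, lambda: phi + x.data * pdf)


def acosh(x: Tensor) -> Tensor:
    """Inverse hyperbolic cosine; caller guarantees argument ≥ 1."""
    x = as_tensor(x)
    return _unary(x, np.arccosh(x.data), lambda: 1.0 / np.sqrt(x.data**2 - 1.0))


def clamp(x: Tensor, lo=None, hi=None) -> Tensor:
    """Clip with gradient masked to the interior (straight-through zero outside)."""
    x = as_tensor(x)
    d = np.clip(x.data, lo, hi)
    mask = np.ones_like(x.data)
    if lo is not None:
        mask = mask * (x.data >= lo)
    if hi is not None:
        mask = mask * (x.data <= hi)
    return _unary(x, d, lambda: mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant shift; softmax invariant
    e = exp(x - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bw)


# ---- grouped 2-D convolution ---------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped cross-correlation. x: (B,Cin,H,W), w: (Cout,Cin/g,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    g = groups
    if Cin % g or Cout % g or Cin // g != Cg:
        raise ValueError(
            f"channel/group mismatch: Cin={Cin}, Cout={Cout}, groups={g}, w expects {Cg} per group"
        )
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    # cols[b, cin, i, j, ho, wo]
    cols = np.empty((B, Cin, kh, kw, Ho, Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s]
    colsg = cols.reshape(B, g, Cg, kh, kw, Ho, Wo)
    wg = w.data.reshape(g, Cout // g, Cg, kh, kw)
    out = _einsum("bgcijhw,gocij->bgohw", colsg, wg)
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def bw(grad):
        gg = grad.reshape(B, g, Cout // g, Ho, Wo)
        if w.requires_grad:
            gw = _einsum("bgohw,bgcijhw->gocij", gg, colsg)
            w._accum(gw.reshape(Cout, Cg, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = _einsum("bgohw,gocij->bgcijhw", gg, wg)
            gcols = gcols.reshape(B, Cin, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcols[:, :, i, j]
            x._accum(gxp[:, :, p : p + H, p : p + W] if p else gxp)

    return Tensor._make(out, parents, bw)


# ---- bilinear resampling -------------------------------------------------

def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Endpoint-aligned linear interpolation matrix (n_out × n_in)."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    for r in range(n_out):
        M[r, lo[r]] += 1.0 - frac[r]
        M[r, hi[r]] += frac[r]
    return M


def upsample_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Resample (B,C,H,W) to (B,C,H',W') with endpoint-aligned bilinear weights."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x
    Rh = _interp_matrix(H, Ho).astype(x.data.dtype)
    Rw = _interp_matrix(W, Wo).astype(x.data.dtype)
    out = _einsum("oh,bchw,pw->bcop", Rh, x.data, Rw)

    def bw(g):
        if x.requires_grad:
            x._accum(_einsum("oh,bcop,pw->bchw", Rh, g, Rw))

    return Tensor._make(out, (x,), bw)


# ---- B-spline edge bank (Kolmogorov-Arnold layers) -----------------------

def bspline_basis(x: np.ndarray, grid: np.ndarray, order: int):
    """Cox–de Boor B-spline basis and its first derivative at points `x`.

    `grid` holds the interior knots (strictly increasing); the knot vector is
    extended by `order` uniform knots on each side. Returns (basis, dbasis),
    each of shape x.shape + (len(grid) + order - 1,).
    """
    k = order
    h0 = grid[1] - grid[0]
    h1 = grid[-1] - grid[-2]
    t = np.concatenate(
        [grid[0] - h0 * np.arange(k, 0, -1), grid, grid[-1] + h1 * np.arange(1, k + 1)]
    )
    xs = np.asarray(x, dtype=np.float64).reshape(-1, 1)
    # order-0 (degree-0) indicator basis
    B = ((xs >= t[:-1]) & (xs < t[1:])).astype(np.float64)
    # make the basis right-continuous at the last knot
    B[:, -1] += (xs[:, 0] == t[-1]).astype(np.float64)
    for d in range(1, k + 1):
        left_den = t[d:-1] - t[: -d - 1]
        right_den = t[d + 1 :] - t[1:-d]
        left = np.where(left_den > 0, (xs - t[: -d - 1]) / np.where(left_den > 0, left_den, 1.0), 0.0)
        right = np.where(right_den > 0, (t[d + 1 :] - xs) / np.where(right_den > 0, right_den, 1.0), 0.0)
        if d == k:  # derivative from the degree-(k-1) basis
            dB = k * (
                np.where(left_den > 0, B[:, :-1] / np.where(left_den > 0, left_den, 1.0), 0.0)
                - np.where(right_den > 0, B[:, 1:] / np.where(right_den > 0, right_den, 1.0), 0.0)
            )
        B = left * B[:, :-1] + right * B[:, 1:]
    shape = np.asarray(x).shape + (B.shape[1],)
    return B.reshape(shape), dB.reshape(shape)


def kan_spline(x: Tensor, coeffs: Tensor, grid: np.ndarray, order: int) -> Tensor:
    """Fused spline part of a KAN layer: y[b,o] = Σ_i Σ_m E[b,i,m]·C[o,i,m].

    E is the B-spline basis at x clipped to the grid, linearly extrapolated
    outside it. x: (B, n_in); coeffs: (n_out, n_in, n_basis).
    """
    x, coeffs = as_tensor(x), as_tensor(coeffs)
    lo, hi = grid[0], grid[-1]
    xc = np.clip(x.data, lo, hi)
    Bm, dBm = bspline_basis(xc, grid, order)
    Bm = Bm.astype(x.data.dtype)
    dBm = dBm.astype(x.data.dtype)
    E = Bm + dBm * (x.data - xc)[..., None]
    out = _einsum("bim,oim->bo", E, coeffs.data)

    def bw(g):
        if coeffs.requires_grad:
            coeffs._accum(_einsum("bo,bim->oim", g, E))
        if x.requires_grad:
            x._accum(_einsum("bo,oim,bim->bi", g, coeffs.data, dBm))

    return Tensor._make(out, (x, coeffs), bw)
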