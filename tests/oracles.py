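"""Independent brute-force oracles used across the test suite.

Everything here is written against the mathematical definitions only —
plain loops and numpy, no calls into the package's computational paths —
so agreement between package and oracle is meaningful.
"""

from __future__ import annotations

import numpy as np


def squared_distance_loop(x, y) -> float:
    return float(sum((a - b) ** 2 for a, b in zip(x, y)))


def grouped_conv_loop(x, w, b, stride, padding, groups):
    """Nested-loop grouped cross-correlation, (B,Cin,H,W)·(Cout,Cin/g,k,k)."""
    B, Cin, H, W = x.shape
    Cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    cg, og = Cin // groups, Cout // groups
    out = np.zeros((B, Cout, Ho, Wo))
    for bb in range(B):
        for o in range(Cout):
            g = o // og
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[bb, g * cg : (g + 1) * cg,
                               i * stride : i * stride + k,
                               j * stride : j * stride + k]
                    out[bb, o, i, j] = float((patch * w[o]).sum()) + b[o]
    return out


def gradient_support_width(kernels, strides, image_size=None) -> int:
    """Empirical receptive field of the centre output unit of a conv chain.

    Builds the chain with all-ones kernels on a one-channel image and
    measures the width of the input region whose perturbation changes the
    centre output — a brute-force check of the receptive-field recursion.
    """
    from tonguedx import autodiff as ad

    if image_size is None:
        image_size = 8
        jump = 1
        rf = 1
        for k, s in zip(kernels, strides):
            rf += (k - 1) * jump
            jump *= s
        image_size = max(image_size, 2 * rf + int(np.prod(strides)) * 4)
    x = ad.tensor(np.zeros((1, 1, image_size, image_size)), requires_grad=True)
    z = x
    for k, s in zip(kernels, strides):
        w = ad.tensor(np.ones((1, 1, k, k)))
        z = ad.conv2d(z, w, stride=s, padding=k // 2)
    _, _, Ho, Wo = z.shape
    grad = np.zeros(z.shape)
    grad[0, 0, Ho // 2, Wo // 2] = 1.0
    z.backward(grad)
    support = np.nonzero(x.grad[0, 0].sum(axis=0))[0]
    return int(support.max() - support.min() + 1)


def average_precision_pr_loop(scores, targets) -> float:
    """AP by explicit precision/recall stepping through all thresholds."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    t = np.asarray(targets)[order]
    n_pos = t.sum()
    ap, tp = 0.0, 0
    prev_recall = 0.0
    for i, hit in enumerate(t):
        if hit:
            tp += 1
            precision = tp / (i + 1)
            recall = tp / n_pos
            ap += precision * (recall - prev_recall)
            prev_recall = recall
    return float(ap)


def auc_concordance_loop(scores, targets) -> float:
    """Mann–Whitney pairwise concordance with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets)
    pos = scores[targets == 1]
    neg = scores[targets == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def kappa_by_hand(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    po = float(np.mean(a == b))
    vals = np.union1d(a, b)
    pe = float(sum(np.mean(a == v) * np.mean(b == v) for v in vals))
    return (po - pe) / (1.0 - pe)


def kan_layer_double_loop(x, coeffs, base_weight, grid, order):
    """Edge-by-edge KAN layer evaluation via the standalone edge function."""
    from tonguedx.kan import KanEdge

    n_out, n_in, _ = coeffs.shape
    out = np.zeros(n_out)
    for o in range(n_out):
        for i in range(n_in):
            edge = KanEdge(coeffs[o, i], grid, order=order,
                           base_weight=base_weight[o, i])
            out[o] += edge(float(x[i]))
    return out


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
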