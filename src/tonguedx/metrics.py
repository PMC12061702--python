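"""Evaluation metrics and annotation-consensus utilities.

Count-based metrics (accuracy, precision, recall, F1) follow the standard
confusion-matrix formulas per label and are macro-averaged; accuracy is
computed element-wise over the label matrix (per binary decision), with
multi-label subset accuracy reported separately where useful. Score-based
metrics (average precision / mAP, ROC-AUC) and Cohen's kappa delegate to
scikit-learn. The consensus utilities implement three-annotator curation:
keep a sample only when all three annotations are identical, and audit a
seeded random fraction of the kept samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, cohen_kappa_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "classification_metrics",
    "average_precision",
    "map_score",
    "auc",
    "cohens_kappa",
    "consensus_filter",
    "audit_sample",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(bool).ravel()
    yp = np.asarray(y_pred).astype(bool).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)), tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)), fn=int(np.sum(yt & ~yp)),
    )


def classification_metrics(counts: ConfusionCounts | list[ConfusionCounts],
                           averaging: str = "macro") -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    A list of per-label counts is macro- or micro-averaged. Zero-denominator
    cells contribute 0 and set ``degenerate=True`` in the report.
    """
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    per = [counts] if isinstance(counts, ConfusionCounts) else list(counts)
    if averaging == "micro" and len(per) > 1:
        per = [ConfusionCounts(
            tp=sum(c.tp for c in per), tn=sum(c.tn for c in per),
            fp=sum(c.fp for c in per), fn=sum(c.fn for c in per))]

    def safe(num, den):
        return (num / den, False) if den > 0 else (0.0, True)

    accs, ps, rs, f1s, degenerate = [], [], [], [], False
    for c in per:
        acc, d0 = safe(c.tp + c.tn, c.n)
        p, d1 = safe(c.tp, c.tp + c.fp)
        r, d2 = safe(c.tp, c.tp + c.fn)
        f1, d3 = safe(2 * p * r, p + r)
        degenerate |= d0 or d1 or d2 or d3
        accs.append(acc); ps.append(p); rs.append(r); f1s.append(f1)
    return {
        "acc": float(np.mean(accs)), "precision": float(np.mean(ps)),
        "recall": float(np.mean(rs)), "f1": float(np.mean(f1s)),
        "degenerate": degenerate,
    }


def average_precision(scores: np.ndarray, targets: np.ndarray) -> float:
    """Average precision (area under the precision-recall step curve)."""
    targets = np.asarray(targets)
    if targets.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(average_precision_score(targets, np.asarray(scores)))


def map_score(scores: np.ndarray, targets: np.ndarray) -> tuple[float, list[int]]:
    """Mean AP over classes; columns are classes. Returns (mAP, skipped classes).

    Classes without a positive instance are skipped and flagged.
    """
    scores = np.atleast_2d(np.asarray(scores))
    targets = np.atleast_2d(np.asarray(targets))
    aps, skipped = [], []
    for j in range(targets.shape[1]):
        if targets[:, j].sum() == 0:
            skipped.append(j)
            continue
        aps.append(average_precision(scores[:, j], targets[:, j]))
    if not aps:
        raise ValueError("no class has a positive instance")
    return float(np.mean(aps)), skipped


def auc(scores: np.ndarray, targets: np.ndarray) -> float:
    """ROC-AUC (trapezoidal; equals the Mann–Whitney concordance statistic)."""
    targets = np.asarray(targets)
    if len(np.unique(targets)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(targets, np.asarray(scores)))


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) between two raters."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("annotations must have equal length >= 2")
    po = float(np.mean(a == b))
    if po == 1.0:
        return 1.0
    # marginal-product expected agreement
    vals = np.union1d(a, b)
    pe = float(sum(np.mean(a == v) * np.mean(b == v) for v in vals))
    if pe == 1.0:
        raise ValueError("expected agreement is 1 with observed disagreement")
    return float(cohen_kappa_score(a, b))


def multilabel_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Macro average of per-label Cohen's kappa for (n, L) label matrices.

    A label on which both raters are constant and identical contributes 1.
    """
    a, b = np.atleast_2d(np.asarray(a)), np.atleast_2d(np.asarray(b))
    ks = []
    for j in range(a.shape[1]):
        aj, bj = a[:, j], b[:, j]
        if np.array_equal(aj, bj):
            ks.append(1.0)
        else:
            ks.append(cohens_kappa(aj, bj))
    return float(np.mean(ks))


def consensus_filter(annotations: tuple[np.ndarray, np.ndarray, np.ndarray]) -> bool:
    """Keep a sample iff all three annotation vectors are exactly equal."""
    a, b, c = (np.asarray(x) for x in annotations)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("annotation vectors must share one label space")
    return bool(np.array_equal(a, b) and np.array_equal(b, c))


def audit_sample(kept_ids: list, fraction: float = 0.10, seed: int = 0) -> list:
    """Seeded random audit subset of ⌈fraction·n⌉ ids, without replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    kept_ids = list(kept_ids)
    if not kept_ids:
        return []
    k = int(np.ceil(fraction * len(kept_ids)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(kept_ids), size=k, replace=False)
    return [kept_ids[i] for i in sorted(idx)]


def evaluate_predictions(scores: np.ndarray, targets: np.ndarray,
                         threshold: float = 0.5) -> dict:
    """Full multi-label report: macro Acc/P/R/F1 at `threshold`, mAP, macro AUC.

    Also reports subset accuracy (exact row match) under ``subset_acc``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    targets = np.atleast_2d(np.asarray(targets))
    pred = scores >= threshold
    per_label = [confusion_counts(targets[:, j], pred[:, j]) for j in range(targets.shape[1])]
    rep = classification_metrics(per_label, averaging="macro")
    try:
        rep["map"], rep["map_skipped"] = map_score(scores, targets)
    except ValueError:
        rep["map"], rep["map_skipped"] = float("nan"), list(range(targets.shape[1]))
    aucs = []
    for j in range(targets.shape[1]):
        if len(np.unique(targets[:, j])) == 2:
            aucs.append(auc(scores[:, j], targets[:, j]))
    rep["auc"] = float(np.mean(aucs)) if aucs else float("nan")
    rep["subset_acc"] = float(np.mean(np.all(pred == targets.astype(bool), axis=1)))
    return rep
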