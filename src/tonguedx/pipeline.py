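"""Training and experiment orchestration.

`train` runs the full dual-space objective (BCE + consistency +
complementarity, each maskable for ablations) with Adam, step-decay
learning rate, He initialisation and seeded shuffling, logging per-epoch
losses and validation metrics as JSON lines and keeping the
best-validation-F1 parameter set. `evaluate` produces the six-metric report
(Acc, P, R, F1, mAP, AUC) per task. The experiment drivers reproduce the
study protocols: the 2×2 constraint ablation grid, nested 25/50/100%
data-fraction runs, and the image-only / text-only / multimodal comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import autodiff as ad
from . import geometry, losses, metrics
from .autodiff import Tensor
from .losses import LossWeights
from .model import ModelConfig, TongueClassifier
from .nn import Adam
from .text_encoder import TextRecord, TextSchema

__all__ = ["RunConfig", "ManifestDataset", "train", "evaluate",
           "run_ablation_grid", "run_fraction_experiment", "run_modality_comparison"]

TASKS = ("pathology", "location")


@dataclass(frozen=True)
class RunConfig:
    """One training run. Default hyperparameters: Adam, lr 1e-3, batch 16,
    300 epochs, step-decay schedule, He initialisation, dropout 0.5."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 300
    max_steps: int | None = None
    lr_schedule: str = "step"
    lr_step_epochs: int = 100
    lr_gamma: float = 0.1
    weight_init: str = "he"
    dropout: float = 0.5
    loss_weights: LossWeights = field(default_factory=LossWeights)
    consistency_enabled: bool = True
    complementarity_enabled: bool = True
    consistency_denominator: str = "plain"
    curvature: float = 1.0
    modality: str = "both"
    data_fraction: float = 1.0
    task: str = "both"
    seed: int = 0
    eval_every: int = 1
    dtype: str = "float64"
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if not 0.0 < self.data_fraction <= 1.0:
            raise ValueError(f"data_fraction must be in (0,1], got {self.data_fraction}")
        if self.modality not in ("both", "image", "text"):
            raise ValueError(f"bad modality {self.modality!r}")
        if self.task not in ("both",) + TASKS:
            raise ValueError(f"bad task {self.task!r}")

    def tasks(self) -> tuple:
        return TASKS if self.task == "both" else (self.task,)


class ManifestDataset:
    """Loads a manifest.jsonl dataset; text is vectorised lazily so an
    image-only run never touches the text records."""

    def __init__(self, manifest_path: str | Path, schema: TextSchema | None = None):
        self.root = Path(manifest_path).parent
        self.schema = schema or TextSchema()
        self.records = [json.loads(line) for line in open(manifest_path)]
        self._images: dict[int, np.ndarray] = {}
        self._text_idx: dict[int, np.ndarray] = {}

    def __len__(self):
        return len(self.records)

    def ids(self, split: str | None = None) -> list[int]:
        return [i for i, r in enumerate(self.records)
                if split is None or r["split"] == split]

    def image(self, i: int) -> np.ndarray:
        if i not in self._images:
            arr = np.asarray(Image.open(self.root / self.records[i]["image"]),
                             dtype=np.float64) / 255.0
            self._images[i] = arr.transpose(2, 0, 1)
        return self._images[i]

    def text_indices(self, i: int) -> np.ndarray:
        if i not in self._text_idx:
            t = self.records[i]["text"]
            rec = TextRecord(attributes=t["attributes"], free_text=t.get("free_text"))
            self._text_idx[i] = self.schema.vectorize(rec)
        return self._text_idx[i]

    def labels(self, i: int, task: str) -> np.ndarray:
        return np.asarray(self.records[i][task], dtype=np.float64)

    def batch(self, idx: list[int], modality: str) -> dict:
        out = {
            "pathology": np.stack([self.labels(i, "pathology") for i in idx]),
            "location": np.stack([self.labels(i, "location") for i in idx]),
        }
        if modality in ("both", "image"):
            out["images"] = np.stack([self.image(i) for i in idx])
        if modality in ("both", "text"):
            out["text"] = np.stack([self.text_indices(i) for i in idx])
        return out

    def any_positive(self, i: int) -> bool:
        r = self.records[i]
        return bool(np.any(r["pathology"]) or np.any(np.asarray(r["location"])[:-1]))


def stratified_fraction(ds: ManifestDataset, ids: list[int], fraction: float,
                        seed: int) -> list[int]:
    """Seeded stratified subsample (strata: any positive label vs none).

    Per-stratum ordering is a fixed permutation of the full id list, so
    subsamples are nested: fraction f1 < f2 implies subset(f1) ⊂ subset(f2).
    """
    if fraction >= 1.0:
        return list(ids)
    rng = np.random.default_rng(seed)
    keep = []
    for flag in (True, False):
        stratum = [i for i in ids if ds.any_positive(i) == flag]
        if not stratum:
            continue
        order = rng.permutation(len(stratum))
        k = max(1, int(np.ceil(fraction * len(stratum))))
        keep.extend(stratum[j] for j in order[:k])
    return sorted(keep)


@dataclass
class TrainResult:
    model: TongueClassifier
    history: list[dict]
    best_state: dict
    best_val_f1: float
    config: RunConfig


def _batch_losses(model: TongueClassifier, batch: dict, cfg: RunConfig):
    """Forward pass + the three loss components (Tensors) on one batch."""
    out = model(batch.get("images"), batch.get("text"), modality=cfg.modality)
    c = cfg.curvature
    # Euclidean prediction loss, averaged over the requested tasks
    l_ce = None
    l_compl = None
    for task in cfg.tasks():
        probs = out[f"prob_{task}"]
        target = Tensor(batch[task])
        term = losses.ce_loss(probs, target)
        l_ce = term if l_ce is None else l_ce + term
        if cfg.complementarity_enabled:
            # scale by 1/sqrt(L) so the whole label simplex maps into a
            # moderate region of the ball (tangent norm <= 1) instead of
            # saturating near the boundary
            scale = 1.0 / np.sqrt(probs.shape[-1])
            y_hs = geometry.exp_map_origin(probs * scale, c=c)
            t_hs = geometry.exp_map_origin(target * scale, c=c)
            d = geometry.hyperbolic_distance(y_hs, t_hs, c=c, validate=False)
            l_compl = d.mean() if l_compl is None else l_compl + d.mean()
    n_tasks = float(len(cfg.tasks()))
    l_ce = l_ce * (1.0 / n_tasks)
    if l_compl is not None:
        l_compl = l_compl * (1.0 / n_tasks)

    l_consis = None
    if cfg.consistency_enabled and cfg.modality == "both":
        zt, zs = out["z_image"], out["z_text"]
        d_es = geometry.euclidean_distance(zt, zs)
        zt_h = geometry.exp_map_origin(zt, c=c)
        zs_h = geometry.exp_map_origin(zs, c=c)
        d_hs = geometry.hyperbolic_distance(zt_h, zs_h, c=c, validate=False)
        l_consis = losses.consistency_loss(d_es, d_hs,
                                           denominator=cfg.consistency_denominator)
    return out, l_ce, l_consis, l_compl


def train(cfg: RunConfig, dataset: ManifestDataset,
          out_dir: str | Path | None = None) -> TrainResult:
    """Train on the manifest's train split; validate on its val split."""
    with ad.default_dtype(cfg.dtype):
        return _train_impl(cfg, dataset, out_dir)


def _train_impl(cfg: RunConfig, dataset: ManifestDataset,
                out_dir: str | Path | None) -> TrainResult:
    rng = np.random.default_rng(cfg.seed)
    model = TongueClassifier(replace(cfg.model, dropout=cfg.dropout), rng,
                             schema=dataset.schema)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    train_ids = dataset.ids("train")
    if cfg.data_fraction < 1.0:
        train_ids = stratified_fraction(dataset, train_ids, cfg.data_fraction, cfg.seed)
    val_ids = dataset.ids("val")
    if not train_ids:
        raise ValueError("empty training split")

    w = cfg.loss_weights
    history: list[dict] = []
    best_state, best_f1 = model.state_dict(), -1.0
    log_file = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_file = open(out_dir / "train_log.jsonl", "w")

    step = 0
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    done = False
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "step":
            opt.lr = cfg.learning_rate * (cfg.lr_gamma ** (epoch // cfg.lr_step_epochs))
        model.train()
        order = shuffle_rng.permutation(len(train_ids))
        ep = {"l_total": [], "l_ce": [], "l_consis": [], "l_compl": []}
        for start in range(0, len(order), cfg.batch_size):
            idx = [train_ids[j] for j in order[start : start + cfg.batch_size]]
            if len(idx) < 2:
                continue  # consistency loss needs >= 2 samples
            batch = dataset.batch(idx, cfg.modality)
            _, l_ce, l_consis, l_compl = _batch_losses(model, batch, cfg)
            total = w.w_ce * l_ce
            if l_consis is not None:
                total = total + w.w_consis * l_consis
            if l_compl is not None:
                total = total + w.w_compl * l_compl
            if not np.isfinite(total.item()):
                parts = {"l_ce": l_ce.item(),
                         "l_consis": None if l_consis is None else l_consis.item(),
                         "l_compl": None if l_compl is None else l_compl.item()}
                raise RuntimeError(f"non-finite loss at step {step}: {parts}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep["l_total"].append(total.item())
            ep["l_ce"].append(l_ce.item())
            ep["l_consis"].append(0.0 if l_consis is None else l_consis.item())
            ep["l_compl"].append(0.0 if l_compl is None else l_compl.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        entry = {"epoch": epoch, "step": step,
                 **{k: float(np.mean(v)) for k, v in ep.items() if v}}
        if val_ids and (epoch % cfg.eval_every == 0 or done or epoch == cfg.epochs - 1):
            rep = evaluate(model, dataset, "val", cfg.task, modality=cfg.modality)
            val_f1 = float(np.mean([rep[t]["f1"] for t in cfg.tasks()]))
            entry["val_macro_f1"] = val_f1
            if val_f1 > best_f1:
                best_f1, best_state = val_f1, model.state_dict()
        history.append(entry)
        if log_file:
            log_file.write(json.dumps(entry) + "\n")
            log_file.flush()
        if done:
            break
    if log_file:
        log_file.close()
    if best_f1 < 0:
        best_state, best_f1 = model.state_dict(), float("nan")
    if out_dir is not None:
        np.savez(Path(out_dir) / "checkpoint.npz", **best_state)
    return TrainResult(model=model, history=history, best_state=best_state,
                       best_val_f1=best_f1, config=cfg)


def evaluate(model: TongueClassifier, dataset: ManifestDataset, split: str,
             task: str = "both", modality: str = "both",
             batch_size: int = 64) -> dict:
    """Six-metric report per task on one split (model in eval mode)."""
    ids = dataset.ids(split)
    if not ids:
        raise ValueError(f"split {split!r} is empty")
    tasks = TASKS if task == "both" else (task,)
    model.eval()
    scores = {t: [] for t in tasks}
    targets = {t: [] for t in tasks}
    with ad.no_grad():
        for start in range(0, len(ids), batch_size):
            idx = ids[start : start + batch_size]
            batch = dataset.batch(idx, modality)
            out = model(batch.get("images"), batch.get("text"), modality=modality)
            for t in tasks:
                scores[t].append(out[f"prob_{t}"].data)
                targets[t].append(batch[t])
    model.train()
    report = {}
    for t in tasks:
        rep = metrics.evaluate_predictions(np.vstack(scores[t]), np.vstack(targets[t]))
        report[t] = {k: rep[k] for k in ("acc", "precision", "recall", "f1", "map", "auc")}
        report[t]["subset_acc"] = rep["subset_acc"]
    return report


def _apply_best(result: TrainResult) -> TongueClassifier:
    result.model.load_state_dict(result.best_state)
    return result.model


# ---- experiment protocols -------------------------------------------------

ABLATION_CONFIGS = (
    ("neither", False, False),
    ("consistency_only", True, False),
    ("complementarity_only", False, True),
    ("both_constraints", True, True),
)


def run_ablation_grid(dataset: ManifestDataset, base_cfg: RunConfig,
                      seeds: tuple = (0, 1, 2, 3, 4)) -> list[dict]:
    """2×2 grid over the consistency/complementarity flags, shared seeds."""
    rows = []
    for name, consis, compl in ABLATION_CONFIGS:
        for seed in seeds:
            cfg = replace(base_cfg, consistency_enabled=consis,
                          complementarity_enabled=compl, seed=seed)
            result = train(cfg, dataset)
            rep = evaluate(_apply_best(result), dataset, "test", cfg.task,
                           modality=cfg.modality)
            rows.append({"config": name, "consistency": consis,
                         "complementarity": compl, "seed": seed, "metrics": rep})
    return rows


def run_fraction_experiment(dataset: ManifestDataset, base_cfg: RunConfig,
                            fractions: tuple = (0.25, 0.5, 1.0),
                            settings: tuple = ("on", "off"),
                            seeds: tuple = (0, 1, 2, 3, 4)) -> list[dict]:
    """Nested data-fraction runs with the dual constraints on and/or off."""
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0,1], got {f}")
    rows = []
    for f in sorted(fractions):
        for setting in settings:
            on = setting == "on"
            for seed in seeds:
                cfg = replace(base_cfg, data_fraction=f, consistency_enabled=on,
                              complementarity_enabled=on, seed=seed)
                result = train(cfg, dataset)
                rep = evaluate(_apply_best(result), dataset, "test", cfg.task,
                               modality=cfg.modality)
                rows.append({"fraction": f, "constraints": setting, "seed": seed,
                             "metrics": rep})
    return rows


def run_modality_comparison(dataset: ManifestDataset, base_cfg: RunConfig,
                            seeds: tuple = (0, 1, 2, 3, 4)) -> list[dict]:
    """image-only vs text-only vs multimodal, shared seeds."""
    rows = []
    for modality in ("image", "text", "both"):
        for seed in seeds:
            cfg = replace(base_cfg, modality=modality, seed=seed,
                          consistency_enabled=base_cfg.consistency_enabled
                          and modality == "both")
            result = train(cfg, dataset)
            rep = evaluate(_apply_best(result), dataset, "test", cfg.task,
                           modality=modality)
            rows.append({"modality": modality, "seed": seed, "metrics": rep})
    return rows


def summarize(rows: list[dict], key: str, task: str, metric: str = "f1") -> dict:
    """Mean metric per group label (e.g. per ablation config or modality)."""
    groups: dict[str, list[float]] = {}
    for r in rows:
        groups.setdefault(str(r[key]), []).append(r["metrics"][task][metric])
    return {k: float(np.mean(v)) for k, v in groups.items()}
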