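# tonguedx

Multimodal, multi-label classification for traditional-Chinese-medicine
(TCM) tongue diagnosis: an RGB tongue photograph and a structured expert
annotation record are fused to predict 10 disease-nature labels (cold, Qi
deficiency, Qi stagnation, heat, dampness, phlegm, blood deficiency, blood
stasis, Yang deficiency, Yin deficiency) and 9 disease-location labels
(intestine, lung, liver, spleen, kidney, stomach, heart, others, healthy).

The package is aimed at researchers who want a tested, CPU-reproducible
reference implementation of this architecture family — including its
hyperbolic-geometry losses and Kolmogorov-Arnold classifier — together with
a seeded synthetic data generator so every stage runs end to end without
any external dataset.

## The model

* **Hierarchical aggregation image encoder** — a 1×1 stem, grouped
  convolutions with receptive fields l(N) = l(N−1) + (k(N)−1)·∏s(i), a
  global-average-pooled context level, and a per-pixel softmax gate that
  mixes levels: Z_t = Σ_N G_N ⊙ Z_t^N.
* **Structured text encoder** — per-attribute embeddings → two-layer MLP →
  Z_s, same dimension as Z_t.
* **Dual-space representation** — embeddings and label vectors are carried
  into the Poincaré ball by the origin exponential map; distances are
  D_es(x,y) = ‖x−y‖² (squared, by convention) and the Poincaré
  d_c(x,y) = (1/√c)·arccosh(1 + 2c‖x−y‖²/((1−c‖x‖²)(1−c‖y‖²))).
* **Fusion** — concat + linear bridge → three affine subspace projections
  F_i = W_i F + b_i → per-subspace multi-scale (height/width/global
  pooling) attention → sum + layer norm.
* **Kolmogorov-Arnold heads** — stacked layers with a learnable univariate
  function on every edge, φ(x) = w·silu(x) + Σ c_m B_m(x) (cubic
  B-splines), node outputs x_{l+1,j} = Σ_i φ_{l,j,i}(x_{l,i}).
* **Losses** — L_total = W_ce·L_ce + W_consis·L_consis + W_compl·L_compl,
  where L_ce is multi-label BCE, L_consis = 1 − cos(d_es, d_hs) compares
  batch vectors of cross-modal distances in the two spaces, and L_compl is
  the Poincaré distance between exp-mapped predictions and targets.

Everything trains on a small numpy reverse-mode autodiff engine included in
the package (`tonguedx.autodiff`) — CPU-only, float64, bit-reproducible
under a fixed seed.

## Worked example

```python
import numpy as np
from tonguedx import (GeneratorConfig, build_dataset, ManifestDataset,
                      RunConfig, ModelConfig, train, evaluate)

cfg_data = GeneratorConfig(n_samples=240, image_size=32, effect_size=2.0,
                           cross_modal_agreement=1.0, seed=11)
build_dataset(cfg_data, "scratch/demo")
ds = ManifestDataset("scratch/demo/manifest.jsonl")

cfg = RunConfig(epochs=12, model=ModelConfig().small(), seed=0)
result = train(cfg, ds, out_dir="scratch/demo_run")
result.model.load_state_dict(result.best_state)
report = evaluate(result.model, ds, "test")
for task, m in report.items():
    print(task, {k: round(v, 3) for k, v in m.items() if k != "subset_acc"})
```

prints (one CPU, ~20 seconds):

```
pathology {'acc': 0.928, 'precision': 0.982, 'recall': 0.728, 'f1': 0.798, 'map': 0.969, 'auc': 0.988}
location {'acc': 0.904, 'precision': 0.848, 'recall': 0.621, 'f1': 0.653, 'map': 0.785, 'auc': 0.894}
```

After 12 epochs on a strongly label-conditional synthetic set the model
ranks labels almost perfectly (AUC 0.99/0.89, mAP 0.97/0.79) while the
0.5-threshold metrics still trail — recall keeps rising with more epochs.
`acc` is the per-decision accuracy over the label matrix;
`f1`/`precision`/`recall` are macro-averages at threshold 0.5; `map` is
mean average precision; `auc` the macro ROC-AUC over labels.

The same flows are available from the shell:

```bash
tonguedx simulate --config cfg.yaml --out data/
tonguedx train --config cfg.yaml --data data/ --out runs/r1
tonguedx evaluate --ckpt runs/r1/checkpoint.npz --data data/ --split test
tonguedx ablate --data data/           # 2x2 consistency/complementarity grid
tonguedx fractions --data data/        # nested 25/50/100% data fractions
tonguedx modality --data data/         # image-only vs text-only vs both
tonguedx consensus --annotations data/annotations.jsonl
```

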