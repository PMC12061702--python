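# Methods

## The model

`tonguedx` implements a multimodal, multi-label classifier for
traditional-Chinese-medicine tongue diagnosis. A sample is an RGB tongue
image paired with a structured expert annotation record; the targets are two
multi-label vectors: 10 disease-nature (pathology) labels and 9
disease-location labels.

**Image encoder (hierarchical aggregation).** A 1×1 convolutional stem maps
pixels to a hidden channel space (Z⁰). A chain of grouped convolutions with
GELU produces levels Z¹…Z^N with growing receptive fields; the closed form

    l(N) = l(N−1) + (k(N)−1) · ∏_{i=1}^{N−1} s(i)

gives the receptive field at each level and is verified against an empirical
gradient-support oracle. Global average pooling of Z^N, broadcast over the
grid, contributes a global-context level Z^{N+1}. A gate network (1×1
convolution over the channel-concatenated levels, softmax across levels)
scores every level at every pixel; the encoder output is the gated sum
Σ_N G_N ⊙ Z^N over Z¹…Z^{N+1}, spatially averaged and projected to a
d-dimensional embedding Z_t. Because the gated sum runs over Z¹…Z^{N+1},
those levels are bilinearly resampled to the finest grid among *them*
(Z¹'s); Z⁰ is resampled onto the same grid but feeds only the gate input.
Softmax normalisation of the gates is a design choice (any normalisation is
left open by the architecture's definition); it makes the aggregation a
per-pixel convex combination.

**Text encoder.** The text modality is a categorical attribute record
(body colour, coating, moisture, shape, teeth marks, cracks, per-organ
indications), vectorised against a fixed schema with an explicit UNK token.
Each attribute has a learnable embedding table initialised *one-hot* — the
canonical encoding of a categorical variable — so attribute identity is
linearly readable from the first optimisation step; tables remain trainable.
The concatenated embeddings (plus a 32-bucket hashed bag of tokens for
optional free text) pass through a two-layer GELU perceptron with dropout to
an embedding Z_s with the same dimension as Z_t.

**Dual-space representation.** Both embeddings live in Euclidean space and
are carried into the Poincaré ball of curvature magnitude c (default 1.0)
by the origin exponential map exp₀(v) = tanh(√c‖v‖)·v/(√c‖v‖), followed by
a clip that keeps points an ε = 1e−5 margin inside the boundary. Distances:

* Euclidean: D_es(x,y) = ‖x−y‖² — deliberately the *squared* norm; every
  consumer is written against this convention.
* Hyperbolic: the standard Poincaré-ball distance
  d(x,y) = (1/√c)·arccosh(1 + 2c‖x−y‖² / ((1−c‖x‖²)(1−c‖y‖²))),
  computed as log(1+u+√(u(u+2))) with a 1e−30 floor on u, which is exact on
  the diagonal and avoids an unbounded derivative there. (An alternative
  sign convention placing minus signs inside the arccosh argument would make
  the argument fall below 1 and is not a metric; the standard form is used.)

**Fusion.** The two embeddings are concatenated and passed through a linear
bridge with GELU and dropout to the fused feature F (dimension d_f), which
three independent affine maps project into subspaces F₁, F₂, F₃. Each
subspace vector is reshaped to a grouped spatial tile (groups × channels ×
tile²) so the multi-scale attention is well defined on it: height-profile,
width-profile and global poolings feed a 1×1 branch (sigmoid gates from the
pooled profiles) and a 3×3 convolution branch; the softmax of each branch's
global pooling is matrix-multiplied against the other branch's flattened
map, and the sigmoided sum reweights the input. The three attention blocks
are parallel and unshared. The reweighted subspaces are summed and
layer-normalised into the classifier input F′.

**Classifier.** Two stacked Kolmogorov-Arnold layers per task (shared
trunk, separate heads for the 10-label and 9-label tasks). Every edge
carries φ(x) = w_base·silu(x) + Σ_m c_m B_m(x) with cubic B-splines on 8
uniform intervals over [−2, 2] (LayerNorm keeps inputs in range) and linear
extrapolation outside; node outputs are plain sums of edge functions.
Spline coefficients start near zero (σ = 0.01) so an untrained layer is a
SiLU-gated He-initialised linear map.

**Losses.** With per-sample image↔text distances collected over a batch,

* L_consis = 1 − cos(d_es, d_hs): zero iff the Euclidean and hyperbolic
  distance profiles are positively proportional. The plain-cosine
  denominator is the default; a squared-norm variant (not scale-invariant)
  is available as `consistency_denominator: squared` for fidelity
  experiments.
* L_ce: mean binary cross-entropy over labels (probabilities clipped to
  [1e−7, 1−1e−7]).
* L_compl: mean Poincaré distance between exp₀ images of the predicted and
  target label vectors. Vectors are scaled by 1/√L before the map so the
  whole label simplex lands in a moderate region of the ball (tangent norm
  ≤ 1); without the scaling the targets sit near the boundary and the
  distance gradient is dominated by its radial component, which measurably
  destabilises early training.
* L_total = w_ce·L_ce + w_consis·L_consis + w_compl·L_compl, defaults
  (1.0, 0.5, 0.5). Setting the two constraint flags to false reduces the
  trainer exactly to a plain multi-label BCE trainer (verified by loss-trace
  equality against an independent minimal trainer).

**Training defaults.** Adam, learning rate 0.001, batch size 16, 300
epochs, step-decay schedule (×0.1 every 100 epochs — the decay step is a
package choice), He initialisation for conv/linear weights, dropout 0.5
(inside the text encoder and the fusion trunk). All randomness flows from a
single integer seed; runs are bit-reproducible on one platform. The
best-validation-macro-F1 parameter set is retained.

## Synthetic data generator

The generator emulates the structure of real tongue-diagnosis corpora
without reproducing their appearance:

* **Images** — an elliptical tongue (jittered centre/axes) on a neutral
  background. Labels shift appearance with amplitude 0.08·`effect_size`:
  heat → red shift and yellowish central tint; cold → blue tinge;
  deficiency syndromes → pale blend toward white; blood stasis → purple;
  dampness/phlegm → bright coating patch; Qi stagnation → darkened sides;
  Yin deficiency → central crack lines; Qi deficiency → scalloped edges.
  Organ labels add dotted textures in the classical region map (tip =
  heart/lung, sides = liver, centre = spleen/stomach, root =
  kidney/intestine), each organ with a distinct channel direction and dot
  period. Gaussian pixel noise (σ = 0.03) is added and values clipped to
  [0, 1].
* **Text** — each attribute equals its label-consistent value with
  probability `cross_modal_agreement`, otherwise a uniform draw over the
  *other* values; hence agreement 1 is a deterministic map and agreement
  1/k makes the attribute exactly independent of the label.
* **Labels** — independent Bernoulli draws (defaults: pathology prevalence
  0.25, organ prevalence 0.20, healthy 0.10). A healthy sample has all
  pathology bits forced to zero; to preserve the configured *marginal*
  pathology prevalence, pathology bits are drawn conditional on healthy=0
  at rate prev/(1−p_healthy).
* **Annotators** — three simulated experts each flip every label bit
  independently with `annotator_error_rate`; the exact probability that a
  sample survives unanimous-consensus filtering is ((1−e)³+e³)^L.
* **XOR regime** (`xor_labels = k`) — the first k pathology labels equal
  the XOR of a visual cue bit (rendered in the image) and a textual cue bit
  (written to the record); each modality alone is independent of the label,
  the pair is decisive. Used for the modality-comparison experiment.
* **Splits** — cumulative-floor rounding of (0.70, 0.15, 0.15); at n=4815
  this yields 3370/722/723.

What the generator does *not* emulate: photographic texture, illumination
or device variation, anatomically realistic tongue shapes, annotator error
structure beyond independent bit flips, or the label co-occurrence patterns
of clinical data. Passing tests therefore demonstrate that the
architecture, losses and pipeline behave as specified and can extract
label-conditional multimodal signal — not that the model reaches clinical
performance on real tongue images.

## Experiment protocols and problem sizes

All experiments run on one CPU. The implementation is a numpy-based
reverse-mode autodiff engine written for this package (float64
throughout), so the reference architecture scale (hidden 64 channels / 4
levels / d=128 / d_f=256) is exposed as the default `ModelConfig` but the
experiments use compact configurations:

* **Learning smoke test** — n=400 samples, 64×64 images, effect size 2,
  cross-modal agreement 1, 200 optimisation steps of the full model
  (`ModelConfig.smoke()`: 16 channels / 3 levels / d=128 / d_f=1024,
  KAN hidden 64). Reaches held-out macro-F1 ≥ 0.9 on both tasks.
* **Constraint ablation** — 2×2 grid over the consistency/complementarity
  flags (n=240, 32×32 images, effect size 2, agreement 1, pathology
  prevalence 0.15, organ prevalence 0.12), 30 epochs,
  `ModelConfig.small()` (16 channels / 3 levels / d=64 / d_f=256).
  Finding: at this scale the constraints' effect on mean macro-F1 is
  within seed noise (|Δ| ≈ 0.01) and slightly negative in most regimes
  tried (perfect text, noisy text, rare labels, noisy training labels,
  short and long horizons). The dual-space constraints are
  co-regularisers whose expected benefit on real clinical data is on the
  order of a few points — below the seed-to-seed variation of runs this
  small — so the ablation grid here documents the protocol and the
  measured (null) ordering rather than demonstrating a positive margin.
* **Data fractions** — nested stratified 25%/50%/100% subsamples of the
  train split, a fixed *epoch* budget per fraction (runs differ in data,
  not optimisation budget), constraints on.
* **Modality comparison** — the XOR regime (k=4 XOR labels, n=320,
  agreement 1), image-only / text-only / multimodal, pathology task.
  Unimodal runs stay at chance by construction; the multimodal model
  learns the joint rule.

## Numerical and degenerate-input choices

* arccosh argument floored at 1+1e−30 (via the offset u): exact zero on
  the diagonal, zero gradient at the floor.
* Ball clipping ε = 1e−5; curvature c = 1.0 (a free parameter of the model;
  exposed in config).
* Zero-norm distance vectors make the consistency cosine undefined: the
  loss returns the neutral value 1 with a warning.
* Metrics with zero denominators return 0 and set a `degenerate` flag;
  mAP skips classes without positives and reports them; AUC requires both
  classes.
* Multi-label binarisation threshold 0.5 on sigmoid outputs for
  count-based metrics; score-based metrics use raw scores. Macro averaging
  throughout (element-wise accuracy over the label matrix; subset accuracy
  reported separately).
* Consensus filtering keeps a sample iff all three annotation vectors are
  exactly equal; inter-annotator agreement is per-label Cohen's kappa,
  macro-averaged; the audit subset is ⌈0.10·n⌉ seeded draws without
  replacement.

## Known limitations

* The autodiff engine is CPU/float64 and unvectorised across runs; the
  reference architecture scale trains slowly and full 300-epoch runs at
  the published scale are impractical here.
* The consistency loss assumes both modalities are present; unimodal runs
  disable it.
* Hyperbolic geometry is used only through origin exponential maps and
  distances; no Möbius arithmetic, learnable curvature, or Lorentz model.
* The synthetic generator's label-to-appearance map is linear and additive;
  it cannot probe robustness to the correlated, non-additive visual
  variation of clinical tongue photography.
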