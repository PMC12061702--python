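"""Label-conditional synthetic tongue-image/text dataset generator.

Real tongue-diagnosis corpora pair an RGB photograph with an expert
annotation record and two multi-label targets: 10 disease-nature
(pathology) labels and 9 disease-location labels. This module emulates that
structure so every pipeline stage is testable without any download:

* images — an elliptical "tongue" on a neutral background whose colour,
  coating and regional texture shift with the active labels (heat → red
  shift, deficiency syndromes → pale shift, dampness/phlegm → bright coating
  patch, each organ → a dotted texture in its TCM region: tip = heart/lung,
  sides = liver, centre = spleen/stomach, root = kidney), plus Gaussian
  pixel noise; the shift amplitude scales with ``effect_size``;
* text — attribute records whose values agree with the labels with
  probability ``cross_modal_agreement`` and are otherwise uniform random;
* annotations — three simulated experts who each flip every label bit
  independently with ``annotator_error_rate``, feeding the consensus
  utilities;
* an optional XOR regime (``xor_labels > 0``) in which the first k pathology
  labels equal the XOR of a visual cue and a text cue, so each modality
  alone is uninformative but the pair is decisive;
* optional training-label noise (``label_noise``), flipping train-split
  target bits from an independent stream — emulates training without
  consensus curation.

Everything is driven by one seeded generator: a config plus seed yields a
byte-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .text_encoder import DEFAULT_SCHEMA, TextRecord

__all__ = [
    "PATHOLOGY_LABELS",
    "LOCATION_LABELS",
    "GeneratorConfig",
    "sample_labels",
    "render_image",
    "render_text",
    "simulate_annotators",
    "build_dataset",
    "split_counts",
    "unanimity_probability",
]

PATHOLOGY_LABELS = (
    "cold", "qi_deficiency", "qi_stagnation", "heat", "dampness",
    "phlegm", "blood_deficiency", "blood_stasis", "yang_deficiency", "yin_deficiency",
)
LOCATION_LABELS = (
    "intestine", "lung", "liver", "spleen", "kidney", "stomach", "heart",
    "others", "healthy",
)
_HEALTHY = LOCATION_LABELS.index("healthy")

# pathology label -> dedicated sign attribute in the text schema
_PATHOLOGY_SIGNS = {
    "cold": "pale_blue_tinge",
    "qi_deficiency": "teeth_marks",
    "qi_stagnation": "sublingual_vein_distension",
    "heat": "yellow_coating",
    "dampness": "greasy_coating",
    "phlegm": "thick_slippery_coating",
    "blood_deficiency": "pale_dry_body",
    "blood_stasis": "ecchymosis_spots",
    "yang_deficiency": "swollen_moist_body",
    "yin_deficiency": "cracks",
}
_LOCATION_SIGNS = {
    "intestine": "sign_intestine", "lung": "sign_lung", "liver": "sign_liver",
    "spleen": "sign_spleen", "kidney": "sign_kidney", "stomach": "sign_stomach",
    "heart": "sign_heart", "others": "atypical_presentation",
}

# organ -> (region, RGB delta direction, dot period) for image texture
_ORGAN_TEXTURE = {
    "heart": ("tip", (1.0, -0.3, -0.3), 2),
    "lung": ("tip", (0.8, 0.8, 0.8), 3),
    "liver": ("sides", (-0.5, 0.6, -0.2), 2),
    "spleen": ("center", (0.6, 0.6, -0.4), 3),
    "stomach": ("center", (-0.4, -0.4, 0.7), 2),
    "kidney": ("root", (-0.2, -0.2, 0.9), 2),
    "intestine": ("root", (-0.6, 0.4, 0.4), 3),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 4815
    split_fractions: tuple = (0.70, 0.15, 0.15)
    image_size: int = 64
    pathology_prevalence: tuple = (0.25,) * 10
    location_prevalence: tuple = (0.20,) * 8 + (0.10,)
    effect_size: float = 1.0
    cross_modal_agreement: float = 0.9
    annotator_error_rate: float = 0.05
    noise_sigma: float = 0.03
    xor_labels: int = 0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        for v in self.pathology_prevalence + self.location_prevalence:
            if not 0.0 < v < 1.0:
                raise ValueError("prevalence values must lie in (0, 1)")
        if len(self.pathology_prevalence) != 10 or len(self.location_prevalence) != 9:
            raise ValueError("need 10 pathology and 9 location prevalence values")
        if not 0.0 <= self.cross_modal_agreement <= 1.0:
            raise ValueError("cross_modal_agreement must be in [0, 1]")
        if not 0.0 <= self.annotator_error_rate < 1.0:
            raise ValueError("annotator_error_rate must be in [0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")


def sample_labels(cfg: GeneratorConfig, rng: np.random.Generator):
    """Draw one (pathology, location) multi-label pair.

    A sample with healthy=1 has all pathology bits forced to 0; to keep the
    configured *marginal* pathology prevalence, pathology bits are drawn
    conditional on healthy=0 with rate prev/(1−p_healthy) (clipped to 1).
    """
    loc = (rng.random(9) < np.asarray(cfg.location_prevalence)).astype(np.int8)
    if loc[_HEALTHY]:
        path = np.zeros(10, dtype=np.int8)
    else:
        p_h = cfg.location_prevalence[_HEALTHY]
        cond = np.minimum(np.asarray(cfg.pathology_prevalence) / (1.0 - p_h), 1.0)
        path = (rng.random(10) < cond).astype(np.int8)
    return path, loc


def _region_masks(size: int, cx: float, cy: float, a: float, b: float):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = (xx - cx) / a
    v = (yy - cy) / b
    tongue = u * u + v * v <= 1.0
    return {
        "tongue": tongue,
        "tip": tongue & (v > 0.45),
        "root": tongue & (v < -0.45),
        "sides": tongue & (np.abs(u) > 0.55) & (np.abs(v) <= 0.45),
        "center": tongue & (np.abs(u) <= 0.55) & (np.abs(v) <= 0.45),
    }, xx, yy


def render_image(pathology: np.ndarray, location: np.ndarray,
                 cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Render one (3, S, S) float image in [0,1], deterministic given rng state."""
    S = cfg.image_size
    alpha = 0.08 * cfg.effect_size
    p = dict(zip(PATHOLOGY_LABELS, np.asarray(pathology, dtype=bool)))
    loc = dict(zip(LOCATION_LABELS, np.asarray(location, dtype=bool)))

    img = np.empty((S, S, 3))
    img[..., 0], img[..., 1], img[..., 2] = 0.35, 0.36, 0.40  # neutral background
    cx = S / 2 + rng.normal(0, 0.02 * S)
    cy = S / 2 + rng.normal(0, 0.02 * S)
    a = S * (0.36 + rng.normal(0, 0.015)) * (1.08 if p["yang_deficiency"] else 1.0)
    b = S * (0.44 + rng.normal(0, 0.015)) * (1.06 if p["yang_deficiency"] else 1.0)
    masks, xx, yy = _region_masks(S, cx, cy, a, b)
    t = masks["tongue"]
    base = np.array([0.78, 0.45, 0.48])
    img[t] = base

    def add(mask, delta):
        img[mask] = img[mask] + np.asarray(delta)

    if p["heat"]:
        add(t, (alpha, -0.2 * alpha, -0.2 * alpha))
        add(masks["center"], (0.4 * alpha, 0.4 * alpha, -0.2 * alpha))  # yellowish tint
    if p["cold"]:
        add(t, (-0.5 * alpha, 0.1 * alpha, alpha))
    for pale in ("qi_deficiency", "blood_deficiency", "yang_deficiency"):
        if p[pale]:
            img[t] = img[t] + 0.45 * alpha * (1.0 - img[t])  # blend toward white
    if p["blood_stasis"]:
        add(t, (0.3 * alpha, -0.5 * alpha, alpha))
    if p["dampness"]:
        add(masks["center"], (0.9 * alpha, 0.9 * alpha, 0.75 * alpha))
    if p["phlegm"]:
        add(masks["center"] | masks["root"], (0.6 * alpha, 0.6 * alpha, 0.6 * alpha))
    if p["qi_stagnation"]:
        add(masks["sides"], (-0.8 * alpha, -0.8 * alpha, -0.3 * alpha))
    if p["yin_deficiency"]:  # central crack lines
        crack = t & (np.abs(xx - cx) < max(1.0, 0.015 * S)) & (np.abs(yy - cy) < 0.8 * b)
        add(crack, (-1.2 * alpha, -1.2 * alpha, -1.2 * alpha))
    if p["qi_deficiency"]:  # scalloped edge marks
        edge = t & (np.abs((xx - cx) / a) > 0.8) & (((yy.astype(int) // 3) % 2) == 0)
        add(edge, (-0.6 * alpha, -0.6 * alpha, -0.6 * alpha))

    for organ, (region, direction, period) in _ORGAN_TEXTURE.items():
        if loc[organ]:
            dots = ((xx.astype(int) // period + yy.astype(int) // period) % 2) == 0
            add(masks[region] & dots, tuple(alpha * d for d in direction))
    if loc["others"]:
        grain = ((xx.astype(int) + 2 * yy.astype(int)) % 5) == 0
        add(t & grain, (0.5 * alpha, 0.5 * alpha, 0.5 * alpha))
    # "healthy" renders as the absence of any regional texture

    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0).transpose(2, 0, 1)


def _consistent_attributes(pathology: np.ndarray, location: np.ndarray) -> dict[str, str]:
    p = dict(zip(PATHOLOGY_LABELS, np.asarray(pathology, dtype=bool)))
    loc = dict(zip(LOCATION_LABELS, np.asarray(location, dtype=bool)))
    attrs = {}
    if p["heat"]:
        attrs["body_color"] = "red"
    elif p["blood_stasis"]:
        attrs["body_color"] = "purple"
    elif p["qi_deficiency"] or p["blood_deficiency"] or p["yang_deficiency"]:
        attrs["body_color"] = "pale"
    else:
        attrs["body_color"] = "pink"
    attrs["coating_thickness"] = "thick" if (p["dampness"] or p["phlegm"]) else "thin"
    attrs["moisture"] = "dry" if p["yin_deficiency"] else ("moist" if p["cold"] or p["yang_deficiency"] else "normal")
    attrs["shape"] = "swollen" if p["yang_deficiency"] else ("thin" if p["blood_deficiency"] else "normal")
    attrs["teeth_marks"] = "present" if p["qi_deficiency"] else "absent"
    attrs["cracks"] = "present" if p["yin_deficiency"] else "absent"
    for label, sign in _PATHOLOGY_SIGNS.items():
        if sign in ("teeth_marks", "cracks"):
            continue
        attrs[sign] = "present" if p[label] else "absent"
    for label, sign in _LOCATION_SIGNS.items():
        attrs[sign] = "present" if loc[label] else "absent"
    return attrs


def render_text(pathology: np.ndarray, location: np.ndarray,
                cfg: GeneratorConfig, rng: np.random.Generator) -> TextRecord:
    """Emit an attribute record; each attribute is label-consistent with
    probability ``cross_modal_agreement`` and uniform random otherwise."""
    attrs = _consistent_attributes(pathology, location)
    out = {}
    for name, value in attrs.items():
        if rng.random() < cfg.cross_modal_agreement:
            out[name] = value
        else:
            # uniform over the *other* values, so P(consistent) = agreement
            # exactly and agreement = 1/k makes the attribute independent of
            # the label
            others = [v for v in DEFAULT_SCHEMA[name] if v != value]
            out[name] = others[rng.integers(len(others))]
    return TextRecord(attributes=out)


def simulate_annotators(labels: np.ndarray, error_rate: float,
                        rng: np.random.Generator):
    """Three independent experts; each flips each label bit with `error_rate`."""
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    labels = np.asarray(labels, dtype=np.int8)
    return tuple(
        np.where(rng.random(labels.shape) < error_rate, 1 - labels, labels)
        for _ in range(3)
    )


def unanimity_probability(error_rate: float, n_labels: int) -> float:
    """Exact P(all three annotations identical) for independent bit flips.

    Per label the three outputs coincide iff all three experts flip or none
    does: (1−e)³ + e³; labels are independent, so the sample-level
    probability is that to the power of the label count.
    """
    e = error_rate
    return float(((1 - e) ** 3 + e**3) ** n_labels)


def split_counts(n: int, fractions: tuple) -> tuple[int, int, int]:
    """Deterministic split sizes by cumulative floor (documented rounding rule).

    train = ⌊f_train·n⌋, val = ⌊(f_train+f_val)·n⌋ − train, test = remainder.
    At n=4815 with (0.70, 0.15, 0.15) this gives 3370/722/723.
    """
    c1 = int(np.floor(fractions[0] * n))
    c2 = int(np.floor((fractions[0] + fractions[1]) * n))
    return c1, c2 - c1, n - c2


def build_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Generate images, manifest.jsonl and annotations.jsonl under `out_dir`.

    Returns the manifest path. Fully reproducible from (cfg, cfg.seed).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    # separate stream: enabling label noise must not perturb images/text/labels
    noise_rng = np.random.default_rng(cfg.seed + 900_001)

    n = cfg.n_samples
    n_train, n_val, _ = split_counts(n, cfg.split_fractions)
    order = rng.permutation(n)
    split_of = np.empty(n, dtype=object)
    split_of[order[:n_train]] = "train"
    split_of[order[n_train : n_train + n_val]] = "val"
    split_of[order[n_train + n_val :]] = "test"

    manifest_path = out_dir / "manifest.jsonl"
    ann_path = out_dir / "annotations.jsonl"
    with open(manifest_path, "w") as mf, open(ann_path, "w") as af:
        for i in range(n):
            if cfg.xor_labels > 0:
                k = cfg.xor_labels
                u = (rng.random(k) < 0.5).astype(np.int8)
                v = (rng.random(k) < 0.5).astype(np.int8)
                path = np.zeros(10, dtype=np.int8)
                path[:k] = u ^ v
                loc = np.zeros(9, dtype=np.int8)
                loc[_HEALTHY] = 1 - int(path.any())
                vis = np.zeros(10, dtype=np.int8)
                vis[:k] = u  # image shows the cue, not the label
                txt = np.zeros(10, dtype=np.int8)
                txt[:k] = v
                img = render_image(vis, np.zeros(9, dtype=np.int8), cfg, rng)
                rec = render_text(txt, np.zeros(9, dtype=np.int8), cfg, rng)
            else:
                path, loc = sample_labels(cfg, rng)
                img = render_image(path, loc, cfg, rng)
                rec = render_text(path, loc, cfg, rng)
            fname = f"img_{i:05d}.png"
            arr = (img.transpose(1, 2, 0) * 255).round().astype(np.uint8)
            Image.fromarray(arr, mode="RGB").save(img_dir / fname)
            # optional single-annotator label noise on the *training* targets
            # (image/text still reflect the true labels); emulates training
            # without consensus curation
            path_out, loc_out = path, loc
            if cfg.label_noise > 0.0 and split_of[i] == "train":
                path_out = np.where(noise_rng.random(10) < cfg.label_noise, 1 - path, path)
                loc_out = np.where(noise_rng.random(9) < cfg.label_noise, 1 - loc, loc)
            mf.write(json.dumps({
                "id": i,
                "image": f"images/{fname}",
                "text": {"attributes": rec.attributes, "free_text": rec.free_text},
                "pathology": path_out.tolist(),
                "location": loc_out.tolist(),
                "split": str(split_of[i]),
            }) + "\n")
            full = np.concatenate([path, loc])
            e1, e2, e3 = simulate_annotators(full, cfg.annotator_error_rate, rng)
            af.write(json.dumps({
                "id": i, "expert1": e1.tolist(), "expert2": e2.tolist(),
                "expert3": e3.tolist(),
            }) + "\n")
    return manifest_path


def with_overrides(cfg: GeneratorConfig, **kwargs) -> GeneratorConfig:
    return replace(cfg, **kwargs)
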