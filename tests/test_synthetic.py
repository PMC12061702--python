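"""Synthetic generator: determinism, prevalence, separation, annotators."""

import hashlib
import json
import numpy as np
import pytest

from tonguedx import metrics
from tonguedx.synthetic import (GeneratorConfig, LOCATION_LABELS,
                                PATHOLOGY_LABELS, build_dataset, render_image,
                                render_text, sample_labels,
                                simulate_annotators, split_counts,
                                unanimity_probability)


def _cfg(**kw):
    return GeneratorConfig(**{"n_samples": 20, "image_size": 32, "seed": 3, **kw})


class TestSampleLabels:
    def test_label_vector_widths(self, rng):
        p, loc = sample_labels(_cfg(), rng)
        assert p.shape == (10,) and loc.shape == (9,)
        assert len(PATHOLOGY_LABELS) == 10 and len(LOCATION_LABELS) == 9

    def test_healthy_forces_pathology_to_zero(self):
        cfg = _cfg(location_prevalence=(0.2,) * 8 + (0.99,),
                   pathology_prevalence=(0.9,) * 10)
        rng = np.random.default_rng(0)
        for _ in range(200):
            p, loc = sample_labels(cfg, rng)
            if loc[-1]:
                assert not p.any()

    def test_marginal_prevalence_within_three_binomial_se(self):
        cfg = _cfg(pathology_prevalence=(0.3,) * 10)
        rng = np.random.default_rng(42)
        n = 10**4
        draws = np.stack([sample_labels(cfg, rng)[0] for _ in range(n)])
        rate = draws.mean(axis=0)
        se = np.sqrt(0.3 * 0.7 / n)
        assert np.all(np.abs(rate - 0.3) <= 3 * se)


class TestRenderImage:
    def test_deterministic_given_seed_and_labels(self):
        cfg = _cfg()
        p = np.array([0, 1, 0, 1, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        loc = np.zeros(9, dtype=np.int8)
        img1 = render_image(p, loc, cfg, np.random.default_rng(9))
        img2 = render_image(p, loc, cfg, np.random.default_rng(9))
        assert np.array_equal(img1, img2)

    def test_shape_and_range(self, rng):
        img = render_image(np.zeros(10), np.zeros(9), _cfg(image_size=48), rng)
        assert img.shape == (3, 48, 48)
        assert img.min() >= 0.0 and img.max() <= 1.0

    @pytest.mark.parametrize("effect,expect_separated", [(0.0, False), (1.0, True)])
    def test_heat_label_shifts_red_channel(self, effect, expect_separated):
        cfg = _cfg(effect_size=effect)
        rng = np.random.default_rng(1)
        n = 120
        heat_on = np.zeros(10); heat_on[PATHOLOGY_LABELS.index("heat")] = 1
        on = [render_image(heat_on, np.zeros(9), cfg, rng)[0].mean() for _ in range(n)]
        off = [render_image(np.zeros(10), np.zeros(9), cfg, rng)[0].mean() for _ in range(n)]
        diff = np.mean(on) - np.mean(off)
        se = np.sqrt(np.var(on) / n + np.var(off) / n)
        if expect_separated:
            assert diff > 3 * se
        else:
            assert abs(diff) <= 3 * se

    def test_separation_grows_with_effect_size(self):
        diffs = []
        for effect in (0.5, 1.0, 2.0):
            cfg = _cfg(effect_size=effect)
            rng = np.random.default_rng(2)
            heat_on = np.zeros(10); heat_on[3] = 1
            on = np.mean([render_image(heat_on, np.zeros(9), cfg, rng)[0].mean()
                          for _ in range(60)])
            off = np.mean([render_image(np.zeros(10), np.zeros(9), cfg, rng)[0].mean()
                           for _ in range(60)])
            diffs.append(on - off)
        assert diffs[0] < diffs[1] < diffs[2]


class TestRenderText:
    def test_full_agreement_is_deterministic_map(self):
        cfg = _cfg(cross_modal_agreement=1.0)
        p = np.zeros(10); p[PATHOLOGY_LABELS.index("heat")] = 1
        rec = render_text(p, np.zeros(9), cfg, np.random.default_rng(0))
        assert rec.attributes["body_color"] == "red"
        assert rec.attributes["yellow_coating"] == "present"

    def test_chance_agreement_makes_attribute_independent_of_label(self):
        # agreement = 1/k: plug-in mutual information ~ 0
        k = 2  # binary sign attributes
        cfg = _cfg(cross_modal_agreement=1.0 / k)
        rng = np.random.default_rng(5)
        n = 10**4
        labels = (rng.random(n) < 0.5).astype(np.int8)
        vals = []
        for lab in labels:
            p = np.zeros(10, dtype=np.int8); p[3] = lab
            rec = render_text(p, np.zeros(9, dtype=np.int8), cfg, rng)
            vals.append(rec.attributes["yellow_coating"] == "present")
        vals = np.asarray(vals)
        joint = np.zeros((2, 2))
        for a in (0, 1):
            for b in (0, 1):
                joint[a, b] = np.mean((labels == a) & (vals == b)) + 1e-12
        mi = (joint * np.log(joint / (joint.sum(1, keepdims=True)
                                      * joint.sum(0, keepdims=True)))).sum()
        assert abs(mi) < 0.005

    def test_same_rng_state_gives_identical_record(self):
        cfg = _cfg(cross_modal_agreement=0.5)
        p = np.ones(10, dtype=np.int8)
        r1 = render_text(p, np.zeros(9), cfg, np.random.default_rng(11))
        r2 = render_text(p, np.zeros(9), cfg, np.random.default_rng(11))
        assert r1.attributes == r2.attributes


class TestSimulateAnnotators:
    def test_zero_error_rate_gives_unanimity(self, rng):
        labels = (rng.random(19) < 0.4).astype(np.int8)
        triple = simulate_annotators(labels, 0.0, rng)
        assert all(np.array_equal(t, labels) for t in triple)
        assert metrics.consensus_filter(triple)

    def test_kept_fraction_matches_exact_unanimity_probability(self):
        e, L, n = 0.05, 19, 10**4
        rng = np.random.default_rng(17)
        kept = 0
        for _ in range(n):
            labels = (rng.random(L) < 0.3).astype(np.int8)
            kept += metrics.consensus_filter(simulate_annotators(labels, e, rng))
        p = unanimity_probability(e, L)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(kept / n - p) <= 3 * se

    def test_pairwise_kappa_decreases_with_error_rate(self):
        rng = np.random.default_rng(23)
        kappas = []
        for e in (0.0, 0.1, 0.3):
            labels = (rng.random((800, 19)) < 0.4).astype(np.int8)
            a = np.where(rng.random(labels.shape) < e, 1 - labels, labels)
            b = np.where(rng.random(labels.shape) < e, 1 - labels, labels)
            kappas.append(metrics.multilabel_kappa(a, b))
        assert kappas[0] > kappas[1] > kappas[2]

    def test_invalid_error_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_annotators(np.zeros(5), 1.0, rng)


class TestBuildDataset:
    def test_split_rounding_rule(self):
        assert split_counts(100, (0.70, 0.15, 0.15)) == (70, 15, 15)
        assert split_counts(4815, (0.70, 0.15, 0.15)) == (3370, 722, 723)

    def test_byte_identical_datasets_from_same_seed(self, tmp_path):
        cfg = _cfg(n_samples=12)
        h = []
        for d in ("a", "b"):
            manifest = build_dataset(cfg, tmp_path / d)
            blob = manifest.read_bytes()
            for img in sorted((tmp_path / d / "images").iterdir()):
                blob += img.read_bytes()
            h.append(hashlib.sha256(blob).hexdigest())
        assert h[0] == h[1]

    def test_manifest_contents_and_split_sizes(self, tmp_path):
        cfg = _cfg(n_samples=20)
        manifest = build_dataset(cfg, tmp_path)
        recs = [json.loads(line) for line in open(manifest)]
        assert len(recs) == 20
        splits = [r["split"] for r in recs]
        assert (splits.count("train"), splits.count("val"), splits.count("test")) \
            == split_counts(20, cfg.split_fractions)
        for r in recs:
            assert len(r["pathology"]) == 10 and len(r["location"]) == 9
            assert (tmp_path / r["image"]).exists()
        ann = [json.loads(line) for line in open(tmp_path / "annotations.jsonl")]
        assert len(ann) == 20 and len(ann[0]["expert1"]) == 19

    def test_xor_mode_labels_are_cue_xor(self, tmp_path):
        cfg = _cfg(n_samples=30, xor_labels=3, cross_modal_agreement=1.0)
        manifest = build_dataset(cfg, tmp_path)
        recs = [json.loads(line) for line in open(manifest)]
        active = np.array([r["pathology"][:3] for r in recs])
        rest = np.array([r["pathology"][3:] for r in recs])
        assert rest.sum() == 0
        assert 0 < active.mean() < 1  # XOR of fair coins: nondegenerate

    def test_label_noise_flips_train_targets_only(self, tmp_path):
        cfg = _cfg(n_samples=60, label_noise=0.4, seed=9)
        clean = _cfg(n_samples=60, label_noise=0.0, seed=9)
        build_dataset(cfg, tmp_path / "noisy")
        build_dataset(clean, tmp_path / "clean")
        noisy = [json.loads(l) for l in open(tmp_path / "noisy" / "manifest.jsonl")]
        ref = [json.loads(l) for l in open(tmp_path / "clean" / "manifest.jsonl")]
        train_flips = sum(
            np.sum(np.asarray(a["pathology"]) != np.asarray(b["pathology"]))
            for a, b in zip(noisy, ref) if a["split"] == "train")
        other_flips = sum(
            np.sum(np.asarray(a["pathology"]) != np.asarray(b["pathology"]))
            for a, b in zip(noisy, ref) if a["split"] != "train")
        assert train_flips > 0 and other_flips == 0

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(split_fractions=(0.5, 0.2, 0.2))
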