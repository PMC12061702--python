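"""Hierarchical aggregation encoder: receptive fields, gating, oracles."""

import numpy as np
import pytest
from oracles import gradient_support_width, grouped_conv_loop

from tonguedx import autodiff as ad
from tonguedx.image_encoder import HANEncoder, LayerSpec, global_context, receptive_field


def _encoder(rng, hidden=4, specs=None, in_channels=3, embed_dim=8):
    return HANEncoder(rng, in_channels=in_channels, hidden_channels=hidden,
                      embed_dim=embed_dim, specs=specs)


class TestReceptiveField:
    @pytest.mark.parametrize("kernels,strides,expected", [
        ((3,), (1,), [3]),
        ((3, 3, 3), (1, 1, 1), [3, 5, 7]),
        ((3, 3), (2, 2), [3, 7]),
        ((5, 3), (1, 1), [5, 7]),
        ((3, 5, 3), (1, 2, 1), [3, 7, 11]),
    ])
    def test_recursion_matches_hand_arithmetic(self, kernels, strides, expected):
        specs = [LayerSpec(k, s, 1, 4) for k, s in zip(kernels, strides)]
        assert receptive_field(specs, l0=1) == expected

    @pytest.mark.parametrize("kernels,strides", [
        ((3,), (1,)), ((3, 3), (1, 1)), ((3, 3, 3), (1, 1, 1)),
        ((3, 3), (2, 1)), ((5, 3), (1, 1)), ((3, 5), (2, 1)),
    ])
    def test_agrees_with_gradient_support_oracle(self, kernels, strides):
        specs = [LayerSpec(k, s, 1, 4) for k, s in zip(kernels, strides)]
        assert receptive_field(specs, l0=1)[-1] == gradient_support_width(kernels, strides)

    def test_empty_specs_give_empty_list(self):
        assert receptive_field([], l0=1) == []

    def test_invalid_l0_raises(self):
        with pytest.raises(ValueError):
            receptive_field([LayerSpec(3, 1, 1, 4)], l0=0)


class TestStemProject:
    def test_identity_weights_reproduce_input(self, rng):
        enc = _encoder(rng, hidden=1, in_channels=1,
                       specs=[LayerSpec(3, 1, 1, 1)])
        enc.stem.weight.data = np.ones((1, 1, 1, 1))
        enc.stem.bias.data = np.zeros(1)
        x = ad.tensor(rng.random((1, 1, 32, 32)))
        assert np.allclose(enc.stem_project(x).data, x.data)

    def test_zero_input_gives_bias(self, rng):
        enc = _encoder(rng)
        enc.stem.bias.data = np.full(4, 0.7)
        out = enc.stem_project(ad.tensor(np.zeros((1, 3, 32, 32))))
        assert np.allclose(out.data, 0.7)

    def test_matches_per_pixel_matvec_oracle(self, rng):
        enc = _encoder(rng)
        x = rng.random((1, 3, 32, 32))
        out = enc.stem_project(ad.tensor(x)).data
        W = enc.stem.weight.data[:, :, 0, 0]  # (hidden, 3)
        expected = np.einsum("oc,bchw->bohw", W, x) + enc.stem.bias.data[None, :, None, None]
        assert np.allclose(out, expected)

    def test_too_small_image_rejected(self, rng):
        enc = _encoder(rng)
        with pytest.raises(ValueError, match="32"):
            enc.stem_project(ad.tensor(np.zeros((1, 3, 16, 16))))


class TestHierarchicalEncode:
    def test_depthwise_averaging_kernel_center_value(self, rng):
        enc = _encoder(rng, hidden=1, in_channels=1, specs=[LayerSpec(3, 1, 1, 1)])
        conv = enc.convs[0]
        conv.weight.data = np.full((1, 1, 3, 3), 1.0 / 9.0)
        conv.bias.data = np.zeros(1)
        x = ad.tensor(np.arange(1.0, 10.0).reshape(1, 1, 3, 3))
        pre = conv(x)
        assert pre.data[0, 0, 1, 1] == pytest.approx(5.0)
        # the level output applies the GELU nonlinearity on top
        assert np.allclose(enc.hierarchical_encode(x)[0].data, ad.gelu(pre).data)

    def test_stride_two_halves_spatial_size(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 2, 2, 4)])
        z0 = ad.tensor(rng.random((1, 4, 8, 8)))
        assert enc.hierarchical_encode(z0)[0].shape == (1, 4, 4, 4)

    def test_matches_grouped_convolution_loop_oracle(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 1, 2, 4)])
        conv = enc.convs[0]
        z0 = rng.normal(size=(2, 4, 6, 6))
        out = conv(ad.tensor(z0)).data
        expected = grouped_conv_loop(z0, conv.weight.data, conv.bias.data, 1, 1, 2)
        assert np.allclose(out, expected)


class TestGlobalContext:
    def test_constant_map_unchanged(self):
        z = ad.tensor(np.full((1, 2, 4, 4), 3.3))
        assert np.allclose(global_context(z).data, 3.3)

    def test_2x2_mean_broadcast(self):
        z = ad.tensor(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        assert np.allclose(global_context(z).data, 2.5)

    def test_matches_mean_oracle(self, rng):
        x = rng.normal(size=(2, 3, 5, 5))
        out = global_context(ad.tensor(x)).data
        assert np.allclose(out[..., 0, 0], x.sum(axis=(2, 3)) / 25.0)


class TestGatedAggregate:
    def _levels(self, rng, enc, n_levels, value=None):
        shape = (1, 4, 8, 8)
        if value is not None:
            return [ad.tensor(np.full(shape, value)) for _ in range(n_levels)]
        return [ad.tensor(rng.normal(size=shape)) for _ in range(n_levels)]

    def test_identical_levels_reproduced_by_convexity(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 1, 2, 4), LayerSpec(3, 1, 2, 4)])
        levels = self._levels(rng, enc, 4, value=1.7)
        agg, gates = enc.gated_aggregate(levels)
        assert np.allclose(agg.data, 1.7)
        assert np.allclose(gates.data.sum(axis=1), 1.0, atol=1e-6)

    def test_one_hot_gate_selects_single_level(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 1, 2, 4), LayerSpec(3, 1, 2, 4)])
        enc.gate.weight.data[:] = 0.0
        enc.gate.bias.data[:] = 0.0
        enc.gate.bias.data[1] = 50.0  # softmax → one-hot on aggregated level 2 (Z²)
        levels = self._levels(rng, enc, 4)
        agg, _ = enc.gated_aggregate(levels)
        assert np.allclose(agg.data, levels[2].data, atol=1e-12)

    def test_matches_per_pixel_weighted_sum_oracle(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 1, 2, 4), LayerSpec(3, 1, 2, 4)])
        levels = self._levels(rng, enc, 4)
        agg, gates = enc.gated_aggregate(levels)
        expected = np.zeros_like(agg.data)
        for j, z in enumerate(levels[1:]):
            expected += gates.data[:, j : j + 1] * z.data
        assert np.allclose(agg.data, expected)

    def test_grid_mismatch_raises(self, rng):
        enc = _encoder(rng, hidden=4, specs=[LayerSpec(3, 1, 2, 4)])
        a = ad.tensor(np.zeros((1, 4, 8, 8)))
        b = ad.tensor(np.zeros((1, 4, 4, 4)))
        with pytest.raises(ValueError, match="grid"):
            enc.gated_aggregate([a, b, a])


class TestEncoderEndToEnd:
    def test_output_is_embedding_vector(self, rng):
        enc = _encoder(rng, hidden=4, embed_dim=6)
        out = enc(ad.tensor(rng.random((2, 3, 32, 32))))
        assert out.shape == (2, 6)

    def test_horizontal_flip_invariance_with_symmetric_kernels(self, rng):
        # stride-1 chain, symmetric (averaging) kernels: a flipped image flips
        # every feature map, and the final spatial pooling removes the flip
        enc = _encoder(rng, hidden=4,
                       specs=[LayerSpec(3, 1, 2, 4), LayerSpec(3, 1, 2, 4)])
        for conv in enc.convs:
            conv.weight.data[:] = 1.0 / 9.0
            conv.bias.data[:] = 0.0
        x = rng.random((1, 3, 32, 32))
        out = enc(ad.tensor(x)).data
        out_flipped = enc(ad.tensor(x[..., ::-1].copy())).data
        assert np.allclose(out, out_flipped, atol=1e-10)
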