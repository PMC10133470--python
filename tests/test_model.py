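"""Model layers vs. independent naive-loop oracles, and variant wiring."""

import numpy as np
import pytest

import oracles
from stgate import nn
from stgate.autodiff import Tensor
from stgate.errors import ConfigurationError
from stgate.graph import knn_graph
from stgate.model import (
    STGATE,
    ConvStack,
    GATLayer,
    ModelConfig,
    SpatialAttention,
    TemporalAttention,
    TLBParams,
    VARIANTS,
    apply_temporal,
)
from stgate.synthetic import make_montage
from stgate.training import cross_entropy

RNG = np.random.default_rng(777)


def small_cfg(variant="stgate"):
    return ModelConfig(
        variant=variant, n_classes=3,
        tlb=TLBParams(conv_channels=8, depth=1, heads=2),
    )


def build_model(variant, n=24, seed=1):
    static = knn_graph(make_montage(n).coords2d, 5)
    model = STGATE(small_cfg(variant), n_channels=n, static_adjacency=static,
                   rng=np.random.default_rng(seed))
    nn.set_dropout_rng(model, np.random.default_rng(2))
    return model


class TestConvStack:
    def test_shape_contract(self):
        stack = ConvStack(8, np.random.default_rng(0))
        out = stack(Tensor(RNG.standard_normal((2, 62, 5, 10))))
        assert out.shape == (2, 62, 8, 6)

    def test_zero_input_zero_biases_gives_zero_output(self):
        stack = ConvStack(4, np.random.default_rng(0))
        out = stack(Tensor(np.zeros((1, 3, 5, 8))))
        assert np.allclose(out.data, 0.0)

    def test_electrode_permutation_equivariance(self):
        stack = ConvStack(4, np.random.default_rng(0))
        x = RNG.standard_normal((2, 6, 5, 9))
        perm = np.random.default_rng(1).permutation(6)
        out = stack(Tensor(x)).data
        out_perm = stack(Tensor(x[:, perm])).data
        assert np.allclose(out_perm, out[:, perm], atol=1e-12)

    def test_wrong_band_axis_is_error(self):
        stack = ConvStack(4, np.random.default_rng(0))
        with pytest.raises(ConfigurationError, match="band"):
            stack(Tensor(np.zeros((1, 3, 4, 8))))
        with pytest.raises(ConfigurationError, match="temporal"):
            stack(Tensor(np.zeros((1, 3, 5, 4))))


class TestTransformer:
    def test_attention_rows_sum_to_one(self):
        enc = nn.TransformerEncoder(6, 8, 2, 2, 16, 0.0, np.random.default_rng(0))
        enc.eval()
        enc(Tensor(RNG.standard_normal((3, 6, 8))))
        for layer in enc.layers:
            att = layer.attn._last_attention
            assert np.allclose(att.sum(axis=-1), 1.0, atol=1e-9)

    def test_depth_zero_is_input_plus_positional_embedding(self):
        enc = nn.TransformerEncoder(5, 4, 0, 1, 8, 0.0, np.random.default_rng(0))
        x = RNG.standard_normal((2, 5, 4))
        out = enc(Tensor(x)).data
        assert np.allclose(out, x + enc.pos.data)

    def test_single_head_layer_matches_dense_oracle(self):
        layer = nn.TransformerEncoderLayer(4, 1, 8, 0.0, np.random.default_rng(3))
        layer.eval()
        x = RNG.standard_normal((2, 3, 4))
        ours = layer(Tensor(x)).data
        theirs = oracles.transformer_layer_loops(x, layer)
        assert np.allclose(ours, theirs, atol=1e-5)

    def test_indivisible_heads_is_configuration_error(self):
        with pytest.raises(ValueError):
            nn.MultiheadSelfAttention(6, 4, np.random.default_rng(0))


class TestSpatialAttention:
    def test_matches_nested_loop_oracle(self):
        b, n, c, t_r = 2, 5, 3, 4
        att = SpatialAttention(n, c, t_r, k_top=2, rng=np.random.default_rng(4))
        xh = RNG.standard_normal((b, n, c, t_r))
        a_std, a_topk, keep = att(Tensor(xh))
        s = oracles.spatial_attention_scores(
            xh, att.v.data, att.w1.data, att.w2.data, att.b.data
        )
        expected_std = oracles.standardize(s)
        assert np.allclose(a_std.data, expected_std, atol=1e-5)
        assert np.allclose(a_topk.data, oracles.topk_rows(expected_std, 2), atol=1e-5)

    def test_zero_parameters_give_zero_scores(self):
        att = SpatialAttention(4, 3, 4, k_top=2, rng=np.random.default_rng(0))
        for p in (att.v, att.w1, att.w2, att.b):
            p.data = np.zeros_like(p.data)
        a_std, _, _ = att(Tensor(RNG.standard_normal((2, 4, 3, 4))))
        assert np.allclose(a_std.data, 0.0)

    def test_every_row_has_k_top_nonzeros(self):
        att = SpatialAttention(24, 8, 6, k_top=10, rng=np.random.default_rng(1))
        _, a_topk, _ = att(Tensor(RNG.standard_normal((3, 24, 8, 6))))
        assert np.all((a_topk.data != 0).sum(axis=-1) == 10)


class TestTemporalAttention:
    def test_matches_nested_loop_oracle(self):
        b, n, c, t_r = 2, 5, 3, 4
        att = TemporalAttention(n, c, t_r, rng=np.random.default_rng(6))
        xh = RNG.standard_normal((b, n, c, t_r))
        out = att(Tensor(xh))
        assert out.shape == (b, t_r, t_r)
        s = oracles.temporal_attention_scores(
            xh, att.v.data, att.u3.data, att.u4.data, att.b.data
        )
        assert np.allclose(out.data, oracles.standardize(s), atol=1e-5)

    def test_zero_weights_give_zero_map(self):
        att = TemporalAttention(4, 3, 4, rng=np.random.default_rng(0))
        for p in (att.v, att.u3, att.u4, att.b):
            p.data = np.zeros_like(p.data)
        out = att(Tensor(RNG.standard_normal((2, 4, 3, 4))))
        assert np.allclose(out.data, 0.0)


class TestApplyTemporal:
    def test_identity_map_is_noop(self):
        xh = RNG.standard_normal((2, 3, 4, 5))
        t_hat = np.broadcast_to(np.eye(5), (2, 5, 5)).copy()
        assert np.allclose(apply_temporal(Tensor(t_hat), Tensor(xh)).data, xh)

    def test_zero_map_gives_zero(self):
        xh = RNG.standard_normal((2, 3, 4, 5))
        out = apply_temporal(Tensor(np.zeros((2, 5, 5))), Tensor(xh))
        assert np.allclose(out.data, 0.0)

    def test_matches_triple_loop_oracle(self):
        xh = RNG.standard_normal((2, 3, 2, 4))
        t_hat = RNG.standard_normal((2, 4, 4))
        ours = apply_temporal(Tensor(t_hat), Tensor(xh)).data
        assert np.allclose(ours, oracles.apply_temporal_loops(t_hat, xh), atol=1e-10)


class TestGATLayer:
    def path_graph_mask(self, b, n=3):
        mask = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            mask[i, i + 1] = mask[i + 1, i] = True
        return np.broadcast_to(mask, (b, n, n)).copy()

    def test_alpha_rows_sum_to_one(self):
        layer = GATLayer(4, 3, heads=2, dropout=0.0, rng=np.random.default_rng(0))
        layer.eval()
        mask = self.path_graph_mask(2, 5)
        layer(Tensor(RNG.standard_normal((2, 5, 4))), mask)
        assert np.allclose(layer._last_alpha.sum(axis=-1), 1.0, atol=1e-9)

    def test_zero_attention_vector_gives_uniform_alpha(self):
        layer = GATLayer(4, 3, heads=1, dropout=0.0, rng=np.random.default_rng(0))
        layer.eval()
        layer.a_src.data[:] = 0.0
        layer.a_dst.data[:] = 0.0
        mask = self.path_graph_mask(1, 4)
        layer(Tensor(RNG.standard_normal((1, 4, 4))), mask)
        alpha = layer._last_alpha[0, 0]
        sizes = mask[0] | np.eye(4, dtype=bool)
        for i in range(4):
            expected = sizes[i] / sizes[i].sum()
            assert np.allclose(alpha[i], expected, atol=1e-9)

    def test_matches_double_loop_oracle(self):
        layer = GATLayer(2, 2, heads=2, dropout=0.0, rng=np.random.default_rng(9))
        layer.eval()
        mask = self.path_graph_mask(2, 3)
        h = RNG.standard_normal((2, 3, 2))
        adjacency = RNG.standard_normal((2, 3, 3))
        ours = layer(Tensor(h), mask, Tensor(adjacency)).data
        theirs = oracles.gat_forward_loops(
            h, mask, layer.w.data, layer.a_src.data, layer.a_dst.data, adjacency
        )
        assert np.allclose(ours, theirs, atol=1e-6)
        # and without the adjacency bias
        ours2 = layer(Tensor(h), mask).data
        theirs2 = oracles.gat_forward_loops(
            h, mask, layer.w.data, layer.a_src.data, layer.a_dst.data
        )
        assert np.allclose(ours2, theirs2, atol=1e-6)


class TestSTGATEWiring:
    def test_logits_shape_and_softmax_normalization(self):
        model = build_model("stgate")
        model.eval()
        logits = model(RNG.standard_normal((3, 24, 5, 10))).data
        assert logits.shape == (3, 3)
        probs = np.exp(logits) / np.exp(logits).sum(axis=-1, keepdims=True)
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_eval_mode_is_deterministic(self):
        model = build_model("stgate")
        model.eval()
        x = RNG.standard_normal((2, 24, 5, 10))
        assert np.array_equal(model(x).data, model(x).data)

    def test_spatial_parameters_matter_only_when_present(self):
        x = RNG.standard_normal((2, 24, 5, 10))
        model = build_model("stgate")
        model.eval()
        before = model(x).data.copy()
        for p in (model.spatial.v, model.spatial.w1, model.spatial.w2):
            p.data = np.zeros_like(p.data)
        after = model(x).data
        assert not np.allclose(before, after)
        tgat = build_model("tgat")
        names = [n for n, _ in tgat.named_parameters()]
        assert not any(n.startswith("spatial") for n in names)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_gradient_reaches_every_parameter_group(self, variant):
        model = build_model(variant)
        model.train()
        logits = model(Tensor(RNG.standard_normal((4, 24, 5, 10))))
        loss = cross_entropy(logits, np.array([0, 1, 2, 0]))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), (
                f"{variant}: no gradient for {name}"
            )

    def test_stgate_parameter_set_is_strict_superset_of_ablations(self):
        full = {n for n, _ in build_model("stgate").named_parameters()}
        for variant in VARIANTS:
            if variant == "stgate":
                continue
            sub = {n for n, _ in build_model(variant).named_parameters()}
            assert sub < full, f"{variant} parameters not a strict subset"

    def test_tgat_without_static_adjacency_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="static"):
            STGATE(small_cfg("tgat"), n_channels=24, rng=np.random.default_rng(0))

    def test_dynamic_adjacency_requires_spatial_attention(self):
        model = build_model("tlb")
        with pytest.raises(ConfigurationError):
            model.dynamic_adjacency(RNG.standard_normal((1, 24, 5, 10)))
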