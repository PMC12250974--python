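"""Architecture contracts: positional encoding, attention, transformer block,
fusion trunk, gradient reversal, classifier heads, and the full forward pass
against an independent loop-based reference."""

import math

import numpy as np
import pytest

from trm_maan import nn
from trm_maan.autodiff import Tensor
from trm_maan.model import (ModelConfig, MultiHeadSelfAttention, TRMMAAN,
                            TransformerBlock, build_model, conv_output_length,
                            positional_encoding)

from reference_impl import (ref_full_forward, ref_multi_head_attention,
                            ref_positional_encoding)


class TestPositionalEncoding:
    def test_first_row_alternates_zero_one(self):
        pe = positional_encoding(4, 6)
        assert np.allclose(pe[0], [0, 1, 0, 1, 0, 1])

    def test_entry_1_0_is_sin_1(self):
        pe = positional_encoding(4, 6)
        assert pe[1, 0] == pytest.approx(math.sin(1.0), abs=1e-12)

    def test_matches_elementwise_loop_oracle(self):
        pe = positional_encoding(8, 6)
        assert np.allclose(pe, ref_positional_encoding(8, 6), atol=1e-9)

    def test_entries_bounded(self):
        pe = positional_encoding(50, 16)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(8, 7)


class TestAttention:
    def cfg(self, D=8, heads=2):
        return ModelConfig(D=D, n_heads=heads, n_layers=1, trunk_channels=2,
                           fc_hidden=4)

    def test_rows_of_attention_matrix_sum_to_one(self, rng):
        attn = MultiHeadSelfAttention(self.cfg(), rng)
        attn(Tensor(rng.normal(size=(2, 5, 8))))
        sums = attn.last_attention.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_token_returns_its_value_vector(self, rng):
        attn = MultiHeadSelfAttention(self.cfg(), rng)
        x = rng.normal(size=(1, 1, 8))
        out = attn(Tensor(x))
        v = x[0, 0] @ attn.W_V.data
        assert np.allclose(out.data[0, 0], v, atol=1e-10)

    def test_matches_brute_force_loop_oracle(self, rng):
        attn = MultiHeadSelfAttention(self.cfg(), rng)
        x = rng.normal(size=(3, 5, 8))
        out = attn(Tensor(x))
        for n in range(3):
            expected = ref_multi_head_attention(
                x[n], attn.W_Q.data, attn.W_K.data, attn.W_V.data, 2)
            assert np.allclose(out.data[n], expected, atol=1e-6)


class TestTransformerBlock:
    def test_output_shape_preserved(self, rng):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=2,
                          fc_hidden=4)
        block = TransformerBlock(cfg, rng)
        out = block(Tensor(rng.normal(size=(2, 6, 8))))
        assert out.shape == (2, 6, 8)

    def test_layernorm_rows_standardized_pre_affine(self, rng):
        ln = nn.LayerNorm(16)
        z = ln.normalized(Tensor(rng.normal(size=(10, 16))))
        assert np.abs(z.data.mean(axis=-1)).max() < 1e-6
        assert np.abs(z.data.var(axis=-1) - 1).max() < 1e-4

    def test_zeroed_ffn_reduces_to_layernorm_of_attention(self, rng):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=2,
                          fc_hidden=4)
        block = TransformerBlock(cfg, rng)
        block.ffn.fc1.weight.data[...] = 0.0
        block.ffn.fc1.bias.data[...] = 0.0
        block.ffn.fc2.weight.data[...] = 0.0
        block.ffn.fc2.bias.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 5, 8)))
        attn_out = block.attn(x)
        expected = block.norm(attn_out)
        assert np.allclose(block(x).data, expected.data, atol=1e-12)


class TestConvProjection:
    def test_shape_contract(self, rng):
        conv = nn.Conv1d(32, 40, 3, 1, rng)
        out = conv(Tensor(rng.normal(size=(1, 32, 1000))))
        assert out.shape == (1, 40, 1000)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        conv = nn.Conv1d(4, 8, 3, 1, rng)
        out = conv(Tensor(np.zeros((2, 4, 20))))
        assert np.allclose(out.data, 0.0)

    def test_kernel_one_identity_construction(self):
        conv = nn.Conv1d(4, 8, 1, 1, np.random.default_rng(0))
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
        for c in range(4):
            conv.weight.data[c, c, 0] = 1.0
        x = np.random.default_rng(1).normal(size=(1, 4, 10))
        out = conv(Tensor(x))
        assert np.allclose(out.data[0, :4], x[0])
        assert np.allclose(out.data[0, 4:], 0.0)

    def test_kernel_longer_than_input_rejected(self, rng):
        conv = nn.Conv1d(2, 4, 7, 1, rng)
        with pytest.raises(ValueError):
            conv(Tensor(np.zeros((1, 2, 5))))


class TestFusionTrunk:
    def test_output_length_follows_pool_arithmetic(self):
        cfg = ModelConfig(D=40, n_heads=4, n_layers=1, trunk_channels=8,
                          fc_hidden=16)
        model = build_model(cfg, n_channels=4, window_len=1000, seed=0)
        # 1000 x 40 map, 2x2 pool -> 500 x 20, times trunk channels
        assert model.trunk.out_dim == 8 * 500 * 20
        fused = model.fused_features(Tensor(np.zeros((1, 4, 1000))),
                                     Tensor(np.zeros((1, 4, 1000))))
        assert fused["eeg"].shape == (1, model.trunk.out_dim)

    def test_trunk_weights_shared_across_modalities(self, tiny_model):
        # the parameter objects used for both branches are identical
        names = [n for n, _ in tiny_model.named_parameters()]
        assert sum(n.startswith("trunk.") for n in names) > 0
        assert not any(n.startswith("trunk_emg") for n in names)
        x = Tensor(np.random.default_rng(0).normal(size=(2, 3, 20)))
        f = tiny_model.fused_features(x, x)
        # identical inputs through the shared trunk give identical outputs
        # up to the per-branch extractors; force identical sequences:
        z = Tensor(np.random.default_rng(1).normal(size=(2, 20, 8)))
        out1 = tiny_model.trunk(z)
        out2 = tiny_model.trunk(z)
        assert np.array_equal(out1.data, out2.data)

    def test_pool_1d_mode_preserves_feature_axis(self):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=2,
                          fc_hidden=4, pool_mode="1d")
        model = build_model(cfg, n_channels=2, window_len=20, seed=0)
        assert model.trunk.out_dim == 2 * 10 * 8


class TestGradientReversal:
    def test_forward_is_identity_bit_exact(self, rng):
        x = Tensor(rng.normal(size=(4, 7)), requires_grad=True)
        assert np.array_equal(nn.gradient_reversal(x, 1.3).data, x.data)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0])
    def test_backward_negates_and_scales_gradient(self, lam, rng):
        # quadratic s(x) = sum(a * x^2): ds/dx = 2 a x, checked at 5 points
        for _ in range(5):
            x0 = rng.normal(size=6)
            a = rng.normal(size=6)
            x = Tensor(x0, requires_grad=True)
            s = (nn.gradient_reversal(x, lam) ** 2.0 * Tensor(a)).sum()
            s.backward()
            expected = -lam * 2.0 * a * x0
            num = 2.0 * a * x0  # analytic unreversed gradient
            assert np.allclose(x.grad, -lam * num, rtol=1e-4)
            assert np.allclose(x.grad, expected, rtol=1e-10)

    def test_lambda_zero_blocks_gradient(self, rng):
        x = Tensor(rng.normal(size=5), requires_grad=True)
        (nn.gradient_reversal(x, 0.0) ** 2.0).sum().backward()
        assert np.allclose(x.grad, 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            nn.gradient_reversal(Tensor(np.zeros(3)), -1.0)


class TestClassifierHeads:
    def test_modal_probabilities_normalized(self, tiny_model, rng):
        f = Tensor(rng.normal(size=(5, tiny_model.trunk.out_dim)))
        probs = tiny_model.modal_head(f)
        assert np.all(probs.data >= 0)
        assert np.allclose(probs.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform(self, tiny_model):
        for p in tiny_model.modal_head.parameters():
            p.data[...] = 0.0
        f = Tensor(np.ones((2, tiny_model.trunk.out_dim)))
        assert np.allclose(tiny_model.modal_head(f).data, 0.5)

    def test_softmax_closed_form(self):
        out = nn.softmax(Tensor(np.array([[2.0, 0.0]])), axis=-1)
        assert np.allclose(out.data, [[0.8808, 0.1192]], atol=1e-4)
        out3 = nn.softmax(Tensor(np.array([[1.0, 1.0, 1.0]])), axis=-1)
        assert np.allclose(out3.data, 1.0 / 3.0)

    def test_workload_head_is_order_sensitive(self, tiny_model, rng):
        fe = rng.normal(size=(1, tiny_model.trunk.out_dim))
        fm = rng.normal(size=(1, tiny_model.trunk.out_dim))
        a = tiny_model.workload_head.logits(Tensor(np.concatenate([fe, fm], axis=1)))
        b = tiny_model.workload_head.logits(Tensor(np.concatenate([fm, fe], axis=1)))
        assert not np.allclose(a.data, b.data)


class TestFullForward:
    def test_matches_loop_reference_implementation(self):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=3,
                          fc_hidden=6)
        model = build_model(cfg, n_channels=3, window_len=16, seed=11)
        rng = np.random.default_rng(5)
        eeg = rng.normal(size=(4, 3, 16))
        emg = rng.normal(size=(4, 3, 16))
        out = model.forward(Tensor(eeg), Tensor(emg))
        expected = ref_full_forward(model, eeg, emg)
        assert np.allclose(out["workload_logits"].data, expected, atol=1e-5)

    def test_matches_reference_with_standard_block(self):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=2, trunk_channels=3,
                          fc_hidden=6, standard_transformer_block=True)
        model = build_model(cfg, n_channels=3, window_len=16, seed=3)
        rng = np.random.default_rng(6)
        eeg = rng.normal(size=(2, 3, 16))
        emg = rng.normal(size=(2, 3, 16))
        out = model.forward(Tensor(eeg), Tensor(emg))
        expected = ref_full_forward(model, eeg, emg)
        assert np.allclose(out["workload_logits"].data, expected, atol=1e-5)

    def test_forward_finite_at_default_init(self, tiny_model, rng):
        out = tiny_model.forward(Tensor(rng.normal(size=(3, 3, 20))),
                                 Tensor(rng.normal(size=(3, 3, 20))))
        for key in ("workload_logits", "modal_logits_eeg", "modal_logits_emg"):
            assert np.all(np.isfinite(out[key].data))

    def test_attention_row_stochastic_at_every_layer(self, rng):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=3, trunk_channels=2,
                          fc_hidden=4)
        model = build_model(cfg, n_channels=2, window_len=12, seed=0)
        model.forward(Tensor(rng.normal(size=(2, 2, 12))),
                      Tensor(rng.normal(size=(2, 2, 12))))
        for blocks in (model.eeg_blocks, model.emg_blocks):
            for block in blocks:
                sums = block.attn.last_attention.sum(axis=-1)
                assert np.allclose(sums, 1.0, atol=1e-6)


class TestVariants:
    def make(self, variant):
        cfg = ModelConfig(D=8, n_heads=2, n_layers=1, trunk_channels=2,
                          fc_hidden=4, variant=variant)
        return build_model(cfg, n_channels=2, window_len=12, seed=0)

    def test_trm_has_no_modal_classifier_parameters(self):
        model = self.make("trm")
        assert not any(n.startswith("modal_head")
                       for n, _ in model.named_parameters())

    def test_maan_never_calls_attention(self, rng):
        model = self.make("maan")
        before = MultiHeadSelfAttention.call_count
        model.forward(Tensor(rng.normal(size=(2, 2, 12))),
                      Tensor(rng.normal(size=(2, 2, 12))))
        assert MultiHeadSelfAttention.call_count == before

    @pytest.mark.parametrize("variant,branch", [("uni_eeg", "eeg"),
                                                ("uni_emg", "emg")])
    def test_unimodal_variants_use_single_branch(self, variant, branch, rng):
        model = self.make(variant)
        x = Tensor(rng.normal(size=(2, 2, 12)))
        out = model.forward(x if branch == "eeg" else None,
                            x if branch == "emg" else None)
        assert out["workload_logits"].shape == (2, 3)
        assert list(out["fused"]) == [branch]

    def test_missing_required_branch_rejected(self, rng):
        model = self.make("trm_maan")
        with pytest.raises(ValueError):
            model.forward(Tensor(rng.normal(size=(1, 2, 12))), None)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="bogus")


class TestModelConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(D=10, n_heads=4)

    def test_head_dims_default_to_d_over_heads(self):
        cfg = ModelConfig(D=8, n_heads=2)
        assert cfg.D_Q == cfg.D_K == cfg.D_V == 4

    def test_roundtrip_dict(self):
        cfg = ModelConfig(D=16, n_heads=4, grl_lambda=0.5)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_conv_output_length(self):
        assert conv_output_length(100, 3, 1) == 100
        assert conv_output_length(100, 5, 2) == 50
        assert conv_output_length(125, 3, 2) == 63

    def test_describe_mentions_all_stages(self, tiny_model):
        text = tiny_model.describe()
        for token in ("conv projection", "transformer", "trunk",
                      "workload classifier", "modal classifier"):
            assert token in text
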