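"""Transformer auto-encoder: encoding, masking, freezing, checkpoints —
plus numerical verification of the autodiff engine it runs on."""

import dataclasses

import numpy as np
import pytest

import gait_ssl as g
from gait_ssl._nn import Adam, Tensor
from gait_ssl.errors import InvalidArgumentError, SchemaError
from gait_ssl.model import MaskSpec, TransformerAutoencoder, sample_mask
from gait_ssl.synthetic import substream


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = g.positional_encoding(4, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_matches_closed_form(self):
        d = 24
        pe = g.positional_encoding(64, d)
        for pos in (0, 1, 7, 63):
            for i in range(d // 2):
                angle = pos / 10000 ** (2 * i / d)
                assert pe[pos, 2 * i] == pytest.approx(np.sin(angle), abs=1e-12)
                assert pe[pos, 2 * i + 1] == pytest.approx(np.cos(angle), abs=1e-12)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)  # ≈ 0.84147

    def test_values_bounded(self):
        pe = g.positional_encoding(64, 24)
        assert np.all(pe >= -1.0) and np.all(pe <= 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(InvalidArgumentError):
            g.positional_encoding(8, 7)


class TestPatchEmbedding:
    def test_reference_token_geometry(self):
        """Window 64 x 18 channels with unit patches -> 64 tokens of length 24."""
        spec = g.ModelSpec()  # reference configuration
        model = TransformerAutoencoder(spec, seed=0)
        tok = model.embed_patches(np.zeros((2, 64, 18), dtype=np.float32))
        assert tok.data.shape == (2, 64, 24)

    def test_affine_property(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=1)
        rng = np.random.default_rng(0)
        a = rng.normal(size=(1, 32, 18)).astype(np.float32)
        b = rng.normal(size=(1, 32, 18)).astype(np.float32)
        e = lambda x: model.embed_patches(x).data
        np.testing.assert_allclose(
            e(a + b), e(a) + e(b) - e(np.zeros_like(a)), atol=1e-4
        )

    def test_zero_window_with_zero_bias_embeds_to_zero(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=1)
        model.embed.b.data[:] = 0.0
        tok = model.embed_patches(np.zeros((1, 32, 18), dtype=np.float32))
        np.testing.assert_allclose(tok.data, 0.0)

    def test_shape_mismatch_rejected(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=1)
        with pytest.raises(SchemaError):
            model.embed_patches(np.zeros((1, 16, 18)))


class TestMasking:
    def test_ten_percent_of_64_patches_is_6(self):
        assert MaskSpec(ratio=0.10).n_masked(64) == 6
        mask = sample_mask(32, 64, MaskSpec(ratio=0.10), substream(0, "m"))
        np.testing.assert_array_equal(mask.sum(axis=1), 6)

    def test_zero_ratio_leaves_tokens_unchanged(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=2)
        x = np.random.default_rng(0).normal(size=(3, 32, 18)).astype(np.float32)
        masked, mask = g.apply_mask(model, x, MaskSpec(ratio=0.0, seed=1))
        assert mask.sum() == 0
        np.testing.assert_array_equal(masked.data, model.embed_patches(x).data)

    def test_full_masking_rejected(self):
        with pytest.raises(InvalidArgumentError, match="visible"):
            MaskSpec(ratio=0.75).n_masked(2)  # round(1.5) = 2 of 2 patches

    def test_deterministic_index_sets(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=2)
        x = np.random.default_rng(1).normal(size=(4, 32, 18)).astype(np.float32)
        _, m1 = g.apply_mask(model, x, MaskSpec(ratio=0.2, seed=9))
        _, m2 = g.apply_mask(model, x, MaskSpec(ratio=0.2, seed=9))
        np.testing.assert_array_equal(m1, m2)

    def test_masked_positions_do_not_influence_output(self, tiny_model_spec):
        """The mask token replaces masked embeddings, so the model's output
        and hence the reconstruction loss against the original values are
        invariant to perturbing the masked-out inputs."""
        model = TransformerAutoencoder(tiny_model_spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 32, 18)).astype(np.float32)
        mask = sample_mask(2, 32, MaskSpec(ratio=0.25), substream(5, "m"))
        out1 = model.forward(x, head="reconstruct", mask=mask).data
        x_pert = x.copy()
        x_pert[mask] += rng.normal(scale=10.0, size=(int(mask.sum()), 18)).astype(np.float32)
        out2 = model.forward(x_pert, head="reconstruct", mask=mask).data
        np.testing.assert_array_equal(out1, out2)
        loss1 = float(np.mean((out1[mask] - x[mask]) ** 2))
        loss2 = float(np.mean((out2[mask] - x[mask]) ** 2))
        assert loss1 == loss2


class TestForward:
    def test_reconstruction_preserves_input_shape(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=0)
        out = model.forward(np.zeros((5, 32, 18), dtype=np.float32), head="reconstruct")
        assert out.data.shape == (5, 32, 18)

    def test_regression_head_maps_to_moment_channels(self):
        spec = g.ModelSpec(
            window=32, n_channels_in=2, n_channels_out=2, d_model=8, n_blocks=2, n_heads=2, ffn_dim=16
        )
        model = TransformerAutoencoder(spec, seed=0)
        out = model.forward(np.zeros((3, 32, 2), dtype=np.float32), head="regress")
        assert out.data.shape == (3, 32, 2)

    def test_patch_length_divides_window(self):
        spec = g.ModelSpec(window=32, patch_length=4, n_channels_in=3, d_model=8, n_blocks=1, n_heads=2, ffn_dim=8)
        model = TransformerAutoencoder(spec, seed=0)
        out = model.forward(np.zeros((1, 32, 3), dtype=np.float32))
        assert out.data.shape == (1, 32, 3)
        with pytest.raises(InvalidArgumentError):
            g.ModelSpec(window=32, patch_length=5)

    def test_evaluation_mode_is_deterministic(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=4)
        x = np.random.default_rng(2).normal(size=(2, 32, 18)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x).data, model.forward(x).data)

    def test_unknown_head_rejected(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=0)
        with pytest.raises(InvalidArgumentError):
            model.forward(np.zeros((1, 32, 18)), head="classify")


class TestFreezing:
    def test_six_of_eight_blocks_is_three_quarters_frozen(self):
        """The reference protocol freezes the first six of eight blocks,
        i.e. ~75% of encoder parameters."""
        model = TransformerAutoencoder(g.ModelSpec(), seed=0)
        frac = g.freeze_prefix(model, 6)
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_zero_frozen_blocks_leaves_all_trainable(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=0)
        g.freeze_prefix(model, 0)
        assert all(p.trainable for p in model.parameters())

    def test_frozen_parameters_survive_an_optimizer_step(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=0)
        g.freeze_prefix(model, 1)
        frozen_before = [p.data.copy() for p in model.blocks[0].parameters()]
        live_before = [p.data.copy() for p in model.blocks[1].parameters()]
        x = np.random.default_rng(0).normal(size=(4, 32, 18)).astype(np.float32)
        opt = Adam(model.parameters(), lr=1e-2)
        out = model.forward(x, head="reconstruct")
        loss = (out - Tensor(x)).square().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        for before, p in zip(frozen_before, model.blocks[0].parameters()):
            np.testing.assert_array_equal(before, p.data)
        assert any(
            not np.array_equal(before, p.data)
            for before, p in zip(live_before, model.blocks[1].parameters())
        )

    def test_out_of_range_rejected(self, tiny_model_spec):
        model = TransformerAutoencoder(tiny_model_spec, seed=0)
        with pytest.raises(InvalidArgumentError):
            g.freeze_prefix(model, 99)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tiny_model_spec, tmp_path):
        model = TransformerAutoencoder(tiny_model_spec, seed=5)
        path = tmp_path / "ckpt.npz"
        g.save_checkpoint(model, path, stage="pretrain", seed=5)
        loaded, meta = g.load_checkpoint(path)
        assert meta["stage"] == "pretrain"
        x = np.random.default_rng(0).normal(size=(2, 32, 18)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x).data, loaded.forward(x).data)

    def test_corrupt_checkpoint_reported(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a checkpoint")
        with pytest.raises(SchemaError, match="corrupt|unreadable"):
            g.load_checkpoint(bad)

    def test_parameter_count_is_spec_function(self, tiny_model_spec):
        a = TransformerAutoencoder(tiny_model_spec, seed=0)
        b = TransformerAutoencoder(tiny_model_spec, seed=123)
        assert a.n_parameters() == b.n_parameters() > 0


class TestAutodiffEngine:
    """Central-difference verification of the full forward graph."""

    @pytest.mark.parametrize("pick", ["embed", "attn_q", "ffn", "layernorm", "mask_token"])
    def test_gradients_match_finite_differences(self, pick):
        spec = g.ModelSpec(
            window=8, patch_length=2, n_channels_in=3, d_model=8, n_blocks=2, n_heads=2, ffn_dim=12, dropout=0.0, n_channels_out=2
        )
        model = TransformerAutoencoder(spec, seed=7)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 3)).astype(np.float32)
        y = rng.normal(size=(2, 8, 2)).astype(np.float32)
        mask = sample_mask(2, spec.n_patches, MaskSpec(ratio=0.25), substream(1, "m"))

        param = {
            "embed": model.embed.w,
            "attn_q": model.blocks[0].attn.q.w,
            "ffn": model.blocks[1].ffn1.w,
            "layernorm": model.blocks[0].ln2.gamma,
            "mask_token": model.mask_token,
        }[pick]
        # promote everything to float64 for an accurate check
        for p in model.parameters():
            p.data = p.data.astype(np.float64)

        def loss_value():
            out = model.forward(x, head="regress", mask=mask)
            return float(((out.data - y) ** 2).mean())

        out = model.forward(x, head="regress", mask=mask)
        loss = (out - Tensor(y.astype(np.float64))).square().mean()
        loss.backward()
        flat_index = np.unravel_index(min(3, param.data.size - 1), param.data.shape)
        analytic = param.grad[flat_index]
        eps = 1e-6
        keep = param.data[flat_index]
        param.data[flat_index] = keep + eps
        up = loss_value()
        param.data[flat_index] = keep - eps
        down = loss_value()
        param.data[flat_index] = keep
        numeric = (up - down) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)
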