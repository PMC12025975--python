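"""Model architecture contracts: gated attention, blocks, encoder,
momentum updates, predictor, reconstructor, heads, checkpoints."""

import numpy as np
import pytest

from aftanet.nn import (Tensor, MultiHeadAttention, softmax, ema_update,
                        AdamW)
from aftanet.model import (ModelConfig, AFTAModel, TokenEmbedder, Encoder,
                           AFTABlock, lr_depth_map)
from aftanet.patching import sample_mask


TINY = ModelConfig.tiny(n_channels=3, n_time_patches=2, patch_len=8,
                        d_model=16, n_heads=2, n_summary=2, n_classes=4)


def tiny_model(**overrides) -> AFTAModel:
    cfg = ModelConfig(**{**TINY.to_dict(), **overrides})
    return AFTAModel(cfg)


def random_patches(n=2, cfg=TINY, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, cfg.n_channels, cfg.n_time_patches,
                            cfg.patch_len))


class TestGatedAttention:
    def test_unit_gate_equals_plain_attention(self):
        rng = np.random.default_rng(0)
        attn = MultiHeadAttention(8, 2, rng)
        x = Tensor(rng.normal(size=(5, 8)))
        plain = attn(x).data
        gated = attn(x, gate=Tensor(np.ones(5))).data
        np.testing.assert_allclose(gated, plain, atol=1e-12)

    def test_single_token_output_is_gated_value_projection(self):
        rng = np.random.default_rng(1)
        attn = MultiHeadAttention(4, 1, rng)
        x = Tensor(rng.normal(size=(1, 4)))
        out = attn(x, gate=Tensor(np.array([2.0])))
        # softmax over one key is exactly 1, so out = W_o (2 * W_v x + b) + b_o
        v = x.data @ attn.w_v.weight.data + attn.w_v.bias.data
        expected = (2.0 * v) @ attn.w_o.weight.data + attn.w_o.bias.data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_attention_rows_normalize(self):
        scores = Tensor(np.random.default_rng(2).normal(size=(6, 6)))
        rows = softmax(scores, axis=-1).data.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_head_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MultiHeadAttention(10, 3, np.random.default_rng(0))


class TestAFTABlock:
    def test_eval_forward_is_repeatable_bitwise(self):
        block = AFTABlock(TINY, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(7, TINY.d_model)))
        a = block(x, training=False).data
        b = block(x, training=False).data
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n_tokens", [2, 5, 11])
    def test_shape_preserved(self, n_tokens):
        block = AFTABlock(TINY, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(2).normal(size=(n_tokens,
                                                         TINY.d_model)))
        assert block(x).shape == (n_tokens, TINY.d_model)

    def test_gradient_reaches_every_learnable_tensor(self):
        block = AFTABlock(TINY, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(3).normal(size=(3, TINY.d_model)))
        out = block(x, training=True)
        (out * out).sum().backward()
        for name, p in block.parameters().items():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestEncoder:
    def test_zero_blocks_is_identity(self):
        cfg = ModelConfig(**{**TINY.to_dict(), "n_blocks": 0})
        enc = Encoder(cfg, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(4, cfg.d_model)))
        np.testing.assert_array_equal(enc(x).data, x.data)

    def test_output_length_matches_input(self):
        enc = Encoder(TINY, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(9, TINY.d_model)))
        assert enc(x).shape == (9, TINY.d_model)

    def test_tiny_preset_deterministic_on_80_tokens(self):
        cfg = ModelConfig.tiny()     # d_model 64, 2 blocks
        enc = Encoder(cfg, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(5).normal(size=(80, 64)))
        a = enc(x, training=False).data
        b = enc(x, training=False).data
        np.testing.assert_array_equal(a, b)

    def test_bypassed_encoder_equals_plain_pre_norm_transformer(self):
        """With the filter gate at alpha=1 and unit frequency gates the
        encoder must coincide with a standard pre-norm Transformer,
        checked against an independent numpy reference."""
        cfg = ModelConfig.tiny(use_freq_gate=False)
        enc = Encoder(cfg, np.random.default_rng(0))
        for block in enc.blocks:
            block.affm.alpha_raw.data = np.array(40.0)   # sigmoid -> 1
        x = np.random.default_rng(1).normal(size=(5, cfg.d_model))
        out = enc(Tensor(x), training=False).data
        from tests_reference import plain_pre_norm_transformer
        ref = plain_pre_norm_transformer(x, enc)
        assert np.max(np.abs(out - ref)) <= 1e-6


class TestMomentumUpdate:
    def test_boundaries_and_arithmetic(self):
        online = {"w": np.array([0.0])}
        old = {"w": np.array([1.0])}
        assert ema_update(online, old, 1.0)["w"] == pytest.approx(1.0)
        assert ema_update(online, old, 0.0)["w"] == pytest.approx(0.0)
        assert ema_update(online, old, 0.9)["w"] == pytest.approx(0.9)

    def test_mismatched_trees_rejected(self):
        with pytest.raises(ValueError):
            ema_update({"a": np.zeros(1)}, {"b": np.zeros(1)}, 0.5)

    def test_momentum_copy_never_receives_gradients(self):
        model = tiny_model()
        target = tiny_model()
        target.load_ssl_state(model.ssl_state())
        patches = random_patches()
        mask = sample_mask(TINY.n_time_patches, TINY.n_channels, 0.5, 0.5,
                           seed=0)
        menc = target.encode_targets(patches, mask)
        assert not menc.requires_grad
        for p in target.parameters().values():
            assert p.grad is None


class TestPredictorReconstructor:
    def _run(self, time_ratio=0.5, channel_ratio=0.5, seed=0):
        model = tiny_model()
        mask = sample_mask(TINY.n_time_patches, TINY.n_channels,
                           time_ratio, channel_ratio, seed=seed)
        out = model.forward_pretrain(random_patches(), mask, training=False)
        return model, mask, out

    def test_one_prediction_vector_per_masked_slot(self):
        _, mask, out = self._run()
        assert out["pred"].shape == (2, mask.n_masked, TINY.d_model)

    def test_empty_mask_gives_empty_outputs(self):
        _, mask, out = self._run(time_ratio=0.0, channel_ratio=0.0)
        assert mask.n_masked == 0
        assert out["pred"].shape == (2, 0, TINY.d_model)
        assert out["rec"].shape == (2, 0, TINY.patch_len)

    def test_reconstruction_has_patch_length(self):
        _, mask, out = self._run()
        assert out["rec"].shape == (2, mask.n_masked, TINY.patch_len)

    def test_eval_forward_deterministic(self):
        model = tiny_model()
        mask = sample_mask(TINY.n_time_patches, TINY.n_channels, 0.5, 0.5,
                           seed=1)
        p = random_patches()
        a = model.forward_pretrain(p, mask, training=False)["rec"].data
        b = model.forward_pretrain(p, mask, training=False)["rec"].data
        np.testing.assert_array_equal(a, b)

    def test_reconstruction_depends_on_predictor_features(self):
        model, mask, out = self._run()
        pred = out["pred"]
        pos = model.embedder.positional_for(mask.masked_pairs)
        n_vis = out["enc"].shape[1] - TINY.n_summary
        from aftanet.nn import concat
        enc_p = out["enc"][:, :n_vis, :]
        pos_vis = model.embedder.positional_for(mask.unmasked_pairs)
        base = model.reconstructor(
            concat([enc_p + pos_vis, pred + pos], axis=1)).data
        # perturb along a random direction (a constant shift would fall in
        # LayerNorm's null space)
        bump = np.random.default_rng(9).normal(size=pred.shape)
        bumped = model.reconstructor(
            concat([enc_p + pos_vis, pred + pos + bump], axis=1)).data
        assert not np.allclose(base, bumped)


class TestHeads:
    def test_class_probabilities_on_simplex(self):
        model = tiny_model()
        probs = model.classify(random_patches(3))
        assert probs.shape == (3, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_four_class_head_outputs_four_probabilities(self):
        # seizure-type classification uses four merged categories
        model = tiny_model(n_classes=4)
        assert model.classify(random_patches(1)).shape == (1, 4)

    def test_regression_head_unconstrained(self):
        model = tiny_model(n_outputs=2)
        out = model.regress_head(model.features(random_patches(3)))
        assert out.shape == (3, 2)

    def test_eval_deterministic(self):
        model = tiny_model()
        p = random_patches(2)
        np.testing.assert_array_equal(model.classify(p), model.classify(p))

    def test_missing_head_rejected(self):
        model = tiny_model(n_classes=None)
        with pytest.raises(RuntimeError):
            model.classify(random_patches(1))


class TestCheckpointAndDepths:
    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        from aftanet.training import save_checkpoint, load_checkpoint

        model = tiny_model()
        model.input_scale = 3.5
        p = random_patches(2)
        before = model.classify(p)
        save_checkpoint(tmp_path / "ck.npz", model)
        back, meta = load_checkpoint(tmp_path / "ck.npz")
        assert back.input_scale == 3.5
        np.testing.assert_allclose(back.classify(p), before, atol=1e-12)

    def test_depth_map_orders_modules(self):
        model = tiny_model()
        depths = lr_depth_map(model)
        assert depths["reg_head.weight"] == 0
        assert depths["encoder.blocks.1.attn.w_q.weight"] == 1
        assert depths["encoder.blocks.0.attn.w_q.weight"] == 2
        assert depths["embedder.w_p"] == TINY.n_blocks + 1

    def test_state_mismatch_rejected(self):
        model = tiny_model()
        state = model.state()
        state.pop(next(iter(state)))
        with pytest.raises(ValueError):
            model.load_state(state)
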