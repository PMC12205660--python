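"""STI model: Siamese weight sharing, attention contracts, ablation wiring,
training behavior and Grad-CAM."""

import dataclasses

import numpy as np
import pytest

from sti_response import (AblationFlags, ConfigError, DataError, StiConfig, StiModel,
                          TrainingConfig, fit, grad_cam, load_model, roc_auc,
                          save_model, train_model)
from sti_response import nn

TINY = StiConfig(patch_shape=(16, 16, 16), embed_dim=32, encoder_channels=(4, 8),
                 n_heads_spatial=2, n_heads_temporal=2, seed=11,
                 training=TrainingConfig(epochs=3, batch_size=8, folds=2))


def _patches(rng, n=4, k=3, shape=(16, 16, 16)):
    return rng.standard_normal((n, 2, k + 1, *shape)).astype(np.float32)


class TestConfig:
    def test_no_timepoint_rejected(self):
        cfg = dataclasses.replace(TINY, ablation=AblationFlags(use_T0=False,
                                                               use_T1=False))
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_no_region_source_rejected(self):
        cfg = dataclasses.replace(TINY, ablation=AblationFlags(
            use_subregions=False, use_whole_tumor=False))
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_heads_must_divide_embed_dim(self):
        cfg = dataclasses.replace(TINY, embed_dim=30, n_heads_spatial=4)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestEncoder:
    def test_eval_forward_is_deterministic(self, rng):
        model = StiModel(TINY)
        model.eval()
        x = _patches(rng)
        a = model.predict_scores(x)
        b = model.predict_scores(x)
        assert np.array_equal(a, b)

    def test_weights_shared_across_regions_and_timepoints(self, rng):
        # Siamese contract: one encoder instance serves every patch; nudging
        # its weights changes the embedding of every region at every timepoint
        model = StiModel(TINY)
        model.eval()
        x = _patches(rng, n=2)
        flat = x.reshape(-1, *x.shape[3:])
        before = model.encode_regions(flat).data.copy()
        model.encoder.norm.beta.data += 1.0
        after = model.encode_regions(flat).data
        assert np.all(np.abs(after - before) > 0.5)
        encoders = [m for m in model.modules() if type(m).__name__ == "RegionEncoder"]
        assert len(encoders) == 1

    def test_zero_patch_gives_finite_embedding(self):
        model = StiModel(TINY)
        emb = model.encode_regions(np.zeros((1, 16, 16, 16), np.float32))
        assert np.all(np.isfinite(emb.data))

    def test_different_patches_do_not_collapse(self, rng):
        model = StiModel(TINY)
        x = rng.standard_normal((2, 16, 16, 16)).astype(np.float32)
        e = model.encode_regions(x).data
        cos = e[0] @ e[1] / (np.linalg.norm(e[0]) * np.linalg.norm(e[1]))
        assert cos < 0.9999


class TestSpatialAttention:
    def test_disabled_gives_exact_token_mean(self, rng):
        cfg = dataclasses.replace(TINY, ablation=AblationFlags(
            use_spatial_attention=False))
        model = StiModel(cfg)
        tokens = nn.Tensor(rng.standard_normal((2, 4, 32)).astype(np.float32))
        out = model.spatial_pool(tokens, [0, 1, 2, 3])
        assert np.allclose(out.data, tokens.data.mean(axis=1), atol=1e-7)

    def test_habitat_permutation_invariance(self, rng):
        # habitats share one token-type encoding, so permuting them must not
        # change the pooled embedding
        model = StiModel(TINY)
        tokens = rng.standard_normal((1, 4, 32)).astype(np.float32)
        perm = tokens[:, [0, 3, 1, 2]]  # whole kept first, habitats permuted
        out1 = model.spatial_pool(nn.Tensor(tokens), [0, 1, 2, 3]).data
        out2 = model.spatial_pool(nn.Tensor(perm), [0, 1, 2, 3]).data
        assert np.allclose(out1, out2, atol=1e-5)

    def test_attention_rows_sum_to_one(self, rng):
        model = StiModel(TINY)
        tokens = nn.Tensor(rng.standard_normal((3, 4, 32)).astype(np.float32))
        model.spatial_pool(tokens, [0, 1, 2, 3])
        w = model.spatial_attn.last_weights
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)

    def test_empty_token_set_raises(self):
        model = StiModel(TINY)
        with pytest.raises(DataError):
            model.spatial_pool(nn.Tensor(np.zeros((1, 0, 32), np.float32)), [])


class TestTemporalAttention:
    def test_equal_embeddings_attend_symmetrically(self, rng):
        model = StiModel(TINY)
        e = nn.Tensor(rng.standard_normal((2, 32)).astype(np.float32))
        model.temporal_fuse(e, e)
        w = model.temporal_attn.last_weights  # (n, heads, 2, 2)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)

    def test_subtract_fusion_is_linear_in_difference(self, rng):
        cfg = dataclasses.replace(
            TINY, fusion_when_no_temporal_attention="subtract",
            ablation=AblationFlags(use_temporal_attention=False))
        model = StiModel(cfg)
        model.subtract_proj.bias.data[:] = 0.0
        a = nn.Tensor(rng.standard_normal((3, 32)).astype(np.float32))
        b = nn.Tensor(rng.standard_normal((3, 32)).astype(np.float32))
        one = model.temporal_fuse(a, b).data
        two = model.temporal_fuse(a + a, b + b).data
        assert np.allclose(two, 2 * one, atol=1e-4)

    def test_concatenate_fusion_used_when_disabled(self, rng):
        cfg = dataclasses.replace(TINY, ablation=AblationFlags(
            use_temporal_attention=False))
        model = StiModel(cfg)
        a = nn.Tensor(rng.standard_normal((2, 32)).astype(np.float32))
        b = nn.Tensor(rng.standard_normal((2, 32)).astype(np.float32))
        expected = np.concatenate([a.data, b.data], axis=-1) \
            @ model.concat_proj.weight.data + model.concat_proj.bias.data
        assert np.allclose(model.temporal_fuse(a, b).data, expected, atol=1e-5)


class TestForward:
    def test_scores_in_unit_interval(self, rng):
        model = StiModel(TINY)
        s = model.predict_scores(_patches(rng, n=6) * 10)
        assert np.all((s >= 0) & (s <= 1))

    def test_untrained_zero_head_scores_half(self, rng):
        model = StiModel(TINY)
        s = model.predict_scores(_patches(rng, n=5))
        assert np.allclose(s, 0.5)

    def test_t0_only_model_ignores_t1(self, rng):
        cfg = dataclasses.replace(TINY, ablation=AblationFlags(use_T1=False))
        model = StiModel(cfg)
        model.head2.weight.data[:] = rng.standard_normal((64, 1)) * 0.5
        x = _patches(rng, n=4)
        s1 = model.predict_scores(x)
        x2 = x.copy()
        x2[:, 1] = rng.standard_normal(x2[:, 1].shape)  # scramble T1
        s2 = model.predict_scores(x2)
        assert np.allclose(s1, s2)

    def test_every_variant_wiring_runs(self, rng):
        from sti_response.experiment import VARIANTS

        x = _patches(rng, n=3)
        for name, flags in VARIANTS.items():
            cfg = dataclasses.replace(TINY, ablation=flags)
            s = StiModel(cfg).predict_scores(x)
            assert s.shape == (3,), name


class TestTraining:
    def test_zero_epochs_returns_initialization(self, rng):
        x = _patches(rng, n=8)
        y = np.array([0, 1] * 4, np.float32)
        cfg = dataclasses.replace(TINY, training=TrainingConfig(epochs=0))
        model = fit(cfg, x, y)
        assert model.checksum() == StiModel(cfg).checksum()
        assert np.allclose(model.predict_scores(x), 0.5)

    def test_learns_planted_difference(self, rng):
        # positives have a mean offset at T1: learnable within a few epochs
        n = 24
        x = rng.standard_normal((n, 2, 4, 16, 16, 16)).astype(np.float32)
        y = np.array([0, 1] * (n // 2), np.float32)
        x[y == 1, 1] += 0.8
        cfg = dataclasses.replace(TINY, training=TrainingConfig(
            epochs=12, batch_size=8, learning_rate=3e-3))
        model = fit(cfg, x, y)
        assert roc_auc(model.predict_scores(x), y) > 0.9

    def test_single_class_raises(self, rng):
        with pytest.raises(DataError):
            fit(TINY, _patches(rng, n=4), np.ones(4, np.float32))

    def test_train_model_grid_selection_is_stratification_invariant(self, rng):
        # duplicating every case must not change the selected grid point
        n = 16
        x = rng.standard_normal((n, 2, 4, 16, 16, 16)).astype(np.float32)
        y = np.array([0, 1] * (n // 2), np.float32)
        x[y == 1] += 0.6
        cfg = dataclasses.replace(TINY, training=TrainingConfig(
            epochs=4, batch_size=8, folds=2,
            grid={"learning_rate": [3e-3, 1e-6]}))
        _, rep1 = train_model(x, y, cfg)
        _, rep2 = train_model(np.tile(x, (2, 1, 1, 1, 1, 1)), np.tile(y, 2), cfg)
        assert rep1["selected"] == rep2["selected"] == {"learning_rate": 3e-3}

    def test_layerwise_unfreeze_runs(self, rng):
        n = 12
        x = rng.standard_normal((n, 2, 4, 16, 16, 16)).astype(np.float32)
        y = np.array([0, 1] * (n // 2), np.float32)
        cfg = dataclasses.replace(TINY, training=TrainingConfig(
            epochs=5, batch_size=6, layerwise_unfreeze=True))
        model = fit(cfg, x[:8], y[:8], x_val=x[8:], y_val=y[8:])
        assert np.all(np.isfinite(model.predict_scores(x)))


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        x = _patches(rng, n=4)
        y = np.array([0, 1, 0, 1], np.float32)
        model = fit(dataclasses.replace(TINY, training=TrainingConfig(epochs=2,
                                                                      batch_size=4)),
                    x, y)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.threshold == model.threshold
        assert np.allclose(loaded.predict_scores(x), model.predict_scores(x))
        assert loaded.config.ablation == model.config.ablation


class TestGradCam:
    def test_maps_normalized_and_shaped(self, rng):
        model = StiModel(TINY)
        model.head2.weight.data[:] = rng.standard_normal((64, 1))
        cams = grad_cam(model, _patches(rng, n=1)[0], target_stage=1)
        assert set(tp for tp, _ in cams) == {"T0", "T1"}
        for cam in cams.values():
            assert cam.shape == (16, 16, 16)
            assert cam.min() >= 0.0 and cam.max() <= 1.0
        assert any(c.max() == pytest.approx(1.0) for c in cams.values())

    def test_zero_input_gives_zero_map(self, rng):
        model = StiModel(TINY)
        model.head2.weight.data[:] = rng.standard_normal((64, 1))
        # zero out the conv biases so a null input produces null activations
        for conv in model.encoder.convs:
            conv.bias.data[:] = 0.0
        x = np.zeros((2, 4, 16, 16, 16), np.float32)
        cams = grad_cam(model, x)
        for cam in cams.values():
            assert not cam.any()

    def test_invalid_stage_raises(self, rng):
        model = StiModel(TINY)
        with pytest.raises(ConfigError):
            grad_cam(model, _patches(rng, n=1)[0], target_stage=9)
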