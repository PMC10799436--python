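"""Attention rollout, feature weighting, deconv decoding, cluster reports."""

import numpy as np
import pytest

from adfuse.attention import AttentionStack
from adfuse.encoder import Encoder3D, EncoderConfig, FeatureMapSet, encode_volume
from adfuse.visualize import (DeconvConfig, attention_rollout, build_deconv,
                              decode_feature, feature_weights,
                              average_feature_weights, residual_augment,
                              salience_contrast, threshold_and_cluster,
                              train_deconv)
from adfuse.volumes import Volume

rng = np.random.default_rng(13)


def random_row_stochastic(n, k=None):
    shape = (n, n) if k is None else (k, n, n)
    w = rng.random(shape)
    return w / w.sum(axis=-1, keepdims=True)


class TestResidualAugment:
    def test_identity_attention_is_fixed_point(self):
        np.testing.assert_allclose(residual_augment(np.eye(3)), np.eye(3))

    def test_uniform_two_token_case(self):
        w = np.full((2, 2), 0.5)
        np.testing.assert_allclose(residual_augment(w),
                                   [[0.75, 0.25], [0.25, 0.75]])

    def test_preserves_row_stochasticity(self):
        w = random_row_stochastic(6)
        a = residual_augment(w)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(a >= 0.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            residual_augment(np.ones((2, 3)))


class TestRollout:
    def test_single_layer_base_case(self):
        w = random_row_stochastic(4)
        out = attention_rollout(w[None])
        np.testing.assert_allclose(out.matrix, residual_augment(w))

    def test_identity_layers_give_identity(self):
        stack = np.stack([np.eye(5)] * 3)
        np.testing.assert_allclose(attention_rollout(stack).matrix, np.eye(5))

    def test_matches_explicit_matrix_product_oracle(self):
        layers = [random_row_stochastic(4) for _ in range(3)]
        out = attention_rollout(np.stack(layers))
        expected = residual_augment(layers[0])
        for w in layers[1:]:
            expected = residual_augment(w) @ expected
        np.testing.assert_allclose(out.matrix, expected, atol=1e-12)
        np.testing.assert_allclose(out.matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_heads_averaged_before_augmentation(self):
        per_head = random_row_stochastic(4, k=3)  # (H, N, N) single layer
        out = attention_rollout(per_head[None])
        np.testing.assert_allclose(out.matrix,
                                   residual_augment(per_head.mean(axis=0)))

    def test_random_stacks_stay_row_stochastic(self):
        for _ in range(10):
            n_layers = int(rng.integers(1, 5))
            n = int(rng.integers(2, 16))
            stack = np.stack([random_row_stochastic(n) for _ in range(n_layers)])
            out = attention_rollout(stack)
            for mat in out.per_layer:
                np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-5)
                assert np.all(mat >= 0.0)


class TestFeatureWeights:
    def test_identity_rollout_gives_uniform_weights_and_first_index(self):
        w = feature_weights(np.eye(4))
        np.testing.assert_allclose(w.weights, 0.25)
        assert w.argmax == 0  # tie -> lowest index

    def test_matches_hand_computed_row_column_means(self):
        a = np.array([[0.6, 0.3, 0.1],
                      [0.2, 0.5, 0.3],
                      [0.1, 0.1, 0.8]])
        w = feature_weights(a)
        expected = 0.5 * (a.mean(axis=0) + a.mean(axis=1))
        np.testing.assert_allclose(w.weights, expected)
        assert w.argmax == int(np.argmax(expected))

    def test_weight_vector_length_equals_token_count(self):
        stack = AttentionStack()
        stack.append(random_row_stochastic(9, k=2)[None])  # (B=1, H=2, 9, 9)
        w = feature_weights(attention_rollout(stack.for_sample(0)))
        assert len(w) == 9
        assert np.all(w.weights >= 0.0)

    def test_average_over_samples_with_correct_only_filter(self):
        stacks = [random_row_stochastic(4)[None] for _ in range(4)]
        all_avg = average_feature_weights(stacks)
        sub_avg = average_feature_weights(stacks, correct=[True, False, True,
                                                           False],
                                          correct_only=True)
        manual = np.mean([feature_weights(attention_rollout(stacks[i])).weights
                          for i in (0, 2)], axis=0)
        np.testing.assert_allclose(sub_avg.weights, manual)
        assert len(all_avg) == 4
        with pytest.raises(ValueError, match="filtered"):
            average_feature_weights(stacks, correct=[False] * 4,
                                    correct_only=True)


class TestDeconv:
    def test_decoder_mirrors_encoder_shape(self, tiny_enc_cfg):
        dec = build_deconv(tiny_enc_cfg, seed=0)
        from adfuse._tensor import Tensor, no_grad
        feats = rng.random((1, 16, 2, 2, 2)).astype(np.float32)
        with no_grad():
            out = dec(Tensor(feats))
        assert out.shape == (1, 1, 16, 16, 16)

    def test_lr_schedule_halves_every_500_epochs(self):
        cfg = DeconvConfig()
        assert cfg.lr_at(1) == pytest.approx(1e-4)
        assert cfg.lr_at(500) == pytest.approx(1e-4)
        assert cfg.lr_at(501) == pytest.approx(5e-5)
        assert cfg.lr_at(1001) == pytest.approx(2.5e-5)

    def test_training_reduces_reconstruction_error(self, tiny_enc_cfg,
                                                   tiny_cohort):
        enc = Encoder3D(tiny_enc_cfg, np.random.default_rng(0))
        dec = build_deconv(tiny_enc_cfg, seed=0, modality="smri")
        vols = np.stack([s.smri.data for s in tiny_cohort[:6]])
        history = train_deconv(dec, enc, vols,
                               DeconvConfig(epochs=15, batch_size=6, lr=1e-3,
                                            lr_step_epochs=10, seed=0))
        assert history[-1] < history[0]

    def test_zero_feature_through_linear_decoder_gives_zero_salience(
            self, tiny_enc_cfg):
        dec = build_deconv(tiny_enc_cfg, seed=1)  # linear: no biases
        feats = FeatureMapSet(np.zeros((16, 2, 2, 2), np.float32), "smri")
        sal = decode_feature(dec, feats, index=3)
        assert np.all(sal.volume.data == 0.0)
        assert sal.volume.shape == (16, 16, 16)
        assert sal.feature_index == 3

    def test_out_of_range_feature_index_rejected(self, tiny_enc_cfg):
        dec = build_deconv(tiny_enc_cfg, seed=0)
        feats = FeatureMapSet(np.zeros((16, 2, 2, 2), np.float32))
        with pytest.raises(IndexError):
            decode_feature(dec, feats, index=16)

    def test_modality_mismatch_rejected(self, tiny_enc_cfg):
        dec = build_deconv(tiny_enc_cfg, seed=0, modality="pet")
        feats = FeatureMapSet(np.zeros((16, 2, 2, 2), np.float32), "smri")
        with pytest.raises(ValueError, match="modality"):
            decode_feature(dec, feats, index=0)

    def test_salience_contrast_requires_both_classes(self, tiny_enc_cfg,
                                                     tiny_cohort):
        enc = Encoder3D(tiny_enc_cfg, np.random.default_rng(0))
        dec = build_deconv(tiny_enc_cfg, seed=0)
        vols = np.stack([s.smri.data for s in tiny_cohort[:3]])
        with pytest.raises(ValueError, match="both classes"):
            salience_contrast(dec, enc, vols, np.ones(3), index=0)


class TestThresholdAndCluster:
    @staticmethod
    def blob_map(shape=(20, 20, 20)):
        """Background noise plus a bright 150-voxel rectangular blob."""
        data = rng.random(shape) * 0.1
        data[2:8, 2:7, 2:7] = 1.0  # 6*5*5 = 150 voxels
        data[4, 4, 4] = 2.0
        return data

    def test_single_blob_reported_with_peak_and_size(self):
        data = self.blob_map()
        # 150 voxels out of 8000 = 1.875%
        report = threshold_and_cluster(data, top_pct=1.875, min_size=100)
        assert len(report) == 1
        cluster = report.clusters[0]
        assert cluster.n_voxels == 150
        assert cluster.peak_ijk == (4, 4, 4)
        assert cluster.peak_intensity == pytest.approx(2.0)

    def test_small_second_blob_filtered_by_size(self):
        data = rng.random((20, 20, 20)) * 0.1
        data[1:7, 1:6, 1:6] = 1.0           # 150 voxels
        data[12:16, 12:17, 12:15] = 1.0     # 4*5*3 = 60 voxels
        report = threshold_and_cluster(data, top_pct=100 * 210 / 8000,
                                       min_size=100)
        assert len(report) == 1
        assert report.clusters[0].n_voxels == 150

    def test_no_filtering_keeps_single_spanning_cluster(self):
        data = rng.random((6, 6, 6))
        report = threshold_and_cluster(data, top_pct=100.0, min_size=0)
        assert len(report) == 1
        assert report.clusters[0].n_voxels == 216

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_and_cluster(np.ones((4, 4, 4)))

    def test_connectivity_6_splits_diagonal_touch(self):
        data = np.zeros((6, 6, 6))
        data[1, 1, 1] = data[2, 2, 2] = 1.0  # touch only diagonally
        rep26 = threshold_and_cluster(data + 1e-6 * rng.random(data.shape),
                                      top_pct=2.0, min_size=0, connectivity=26)
        rep6 = threshold_and_cluster(data + 1e-6 * rng.random(data.shape),
                                     top_pct=2.0, min_size=0, connectivity=6)
        sizes26 = sorted(c.n_voxels for c in rep26.clusters)
        sizes6 = sorted(c.n_voxels for c in rep6.clusters)
        assert max(sizes26) >= 2
        assert max(sizes6) == 1

    def test_mm_coordinates_follow_affine(self):
        data = self.blob_map()
        vol = Volume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
        report = threshold_and_cluster(vol, top_pct=1.875, min_size=100)
        np.testing.assert_allclose(report.clusters[0].peak_mm, [8.0, 8.0, 8.0])

    def test_report_frame_has_table_columns(self):
        report = threshold_and_cluster(self.blob_map(), top_pct=1.875,
                                       min_size=100)
        df = report.to_frame()
        assert list(df.columns) == ["rank", "peak_x_mm", "peak_y_mm",
                                    "peak_z_mm", "peak_voxel_ijk",
                                    "peak_intensity", "voxels"]
        assert df.loc[0, "rank"] == 1
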