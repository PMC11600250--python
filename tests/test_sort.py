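"""Sorter contracts: clustering math, training behavior, artifact filter."""

import copy

import numpy as np
import pytest

from measort.evaluate import match_accuracy
from measort.sort import (
    NetworkSpec,
    TrainConfig,
    ae_ensemble_sort,
    deep_ae_sort,
    finetune_autoencoder,
    overcluster_artifact_filter,
    pretrain_autoencoder,
    soft_assign,
    target_distribution,
    train_dec,
    train_idec,
)


class TestSoftAssign:
    def test_point_on_centroid_dominates(self):
        z = np.array([[0.0, 0.0]])
        mu = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        q = soft_assign(z, mu, alpha=1.0)
        assert q[0, 0] > 0.98
        assert q[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_equidistant_symmetry(self):
        q = soft_assign(np.array([[0.0]]), np.array([[-1.0], [1.0]]), 1.0)
        np.testing.assert_allclose(q, [[0.5, 0.5]], atol=1e-12)

    def test_hand_computed_kernel_values(self):
        # squared distances 1 and 3 with alpha=1: s = [1/2, 1/4] -> q = [2/3, 1/3]
        z = np.array([[0.0]])
        mu = np.array([[1.0], [np.sqrt(3.0)]])
        q = soft_assign(z, mu, alpha=1.0)
        np.testing.assert_allclose(q, [[2.0 / 3.0, 1.0 / 3.0]], atol=1e-9)

    def test_single_centroid_rejected(self):
        with pytest.raises(ValueError):
            soft_assign(np.zeros((3, 2)), np.zeros((1, 2)), 1.0)


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_single_row_identity(self):
        q = np.array([[0.3, 0.2, 0.5]])
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_uniform_stays_uniform(self):
        q = np.full((4, 5), 0.2)
        np.testing.assert_allclose(target_distribution(q), q, atol=1e-12)

    def test_sharpens_confident_assignments(self):
        # f = [1.5, 0.5]; row 0 weights [0.81/1.5, 0.01/0.5] -> ~[0.96, 0.04]
        q = np.array([[0.9, 0.1], [0.6, 0.4]])
        p = target_distribution(q)
        assert p[0, 0] > 0.95
        np.testing.assert_allclose(p[0], [0.54 / 0.56, 0.02 / 0.56], atol=1e-12)

    def test_zero_column_excluded(self):
        q = np.array([[0.5, 0.5, 0.0], [0.6, 0.4, 0.0]])
        p = target_distribution(q)
        assert np.all(p[:, 2] == 0.0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestPretrainAutoencoder:
    def test_training_reduces_reconstruction_error(self, two_blob_features,
                                                   small_spec, quick_config):
        X, _ = two_blob_features
        ae, hist = pretrain_autoencoder(X, small_spec, quick_config)
        assert hist["pretrain_loss"][-1] < hist["initial_loss"]

    def test_constant_dataset_reconstructed_near_perfectly(self, small_spec):
        X = np.tile(np.linspace(-1, 1, 63), (200, 1))
        cfg = TrainConfig(pretrain_epochs=40, batch_size=64, seed=1)
        ae, hist = pretrain_autoencoder(X, small_spec, cfg)
        assert hist["pretrain_loss"][-1] < 1e-3

    def test_blob_embedding_is_well_separated(self, two_blob_features,
                                              small_spec, quick_config):
        from sklearn.metrics import silhouette_score

        X, y = two_blob_features
        ae, _ = pretrain_autoencoder(X, small_spec, quick_config)
        from measort.sort import _standardize

        z = ae.encode(_standardize(X)[0])
        assert silhouette_score(z, y) > 0.5

    def test_same_seed_reproduces_losses(self, two_blob_features, small_spec,
                                         quick_config):
        X, _ = two_blob_features
        _, h1 = pretrain_autoencoder(X, small_spec, quick_config)
        _, h2 = pretrain_autoencoder(X, small_spec, quick_config)
        assert h1["pretrain_loss"] == h2["pretrain_loss"]

    def test_dimension_mismatch_rejected(self, small_spec, quick_config):
        with pytest.raises(ValueError):
            pretrain_autoencoder(np.zeros((10, 10)), small_spec, quick_config)


class TestDeepSorters:
    def test_dec_separates_two_blobs_perfectly(self, two_blob_features,
                                               small_spec, quick_config):
        X, y = two_blob_features
        result = train_dec(X, small_spec, quick_config, K=2)
        assert match_accuracy(result.labels, y).accuracy == 1.0
        np.testing.assert_allclose(result.soft_assignments.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_idec_separates_two_blobs(self, two_blob_features, small_spec,
                                      quick_config):
        X, y = two_blob_features
        result = train_idec(X, small_spec, quick_config, K=2)
        assert match_accuracy(result.labels, y).accuracy == 1.0
        np.testing.assert_allclose(result.soft_assignments.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_tol_one_stops_before_any_finetuning(self, two_blob_features,
                                                 small_spec, quick_config):
        X, _ = two_blob_features
        cfg = TrainConfig(**{**quick_config.__dict__, "tol": 1.0})
        result = train_dec(X, small_spec, cfg, K=2)
        assert result.history["stopped_at"] == 0

    def test_k_larger_than_n_rejected(self, small_spec, quick_config):
        with pytest.raises(ValueError):
            train_dec(np.zeros((4, 63)), small_spec, quick_config, K=5)

    def test_idec_gamma_zero_equals_continued_autoencoder_training(
        self, two_blob_features, small_spec, quick_config
    ):
        """With γ=0 the IDEC update path must reduce to plain reconstruction
        training: encoder and decoder weight trajectories coincide."""
        X, _ = two_blob_features
        cfg = TrainConfig(**{**quick_config.__dict__, "gamma": 0.0,
                             "finetune_iterations": 60, "update_interval": 100})
        from measort.sort import _standardize

        x = _standardize(X)[0]
        ae0, _ = pretrain_autoencoder(x, small_spec, cfg, standardized=True)
        idec = train_idec(X, small_spec, cfg, K=2,
                          pretrained=copy.deepcopy(ae0))
        plain = finetune_autoencoder(copy.deepcopy(ae0), X, cfg)
        for w_idec, w_plain in zip(idec.model.autoencoder.params, plain.params):
            np.testing.assert_array_equal(w_idec, w_plain)

    def test_deep_ae_sort_perfect_point_clusters_and_determinism(
        self, small_spec, quick_config
    ):
        rng = np.random.default_rng(1)
        centers = rng.normal(0, 5, size=(3, 63))
        X = np.repeat(centers, 60, axis=0) + rng.normal(0, 0.01, (180, 63))
        y = np.repeat(np.arange(3), 60)
        r1 = deep_ae_sort(X, small_spec, quick_config, K=3)
        r2 = deep_ae_sort(X, small_spec, quick_config, K=3)
        assert match_accuracy(r1.labels, y).accuracy == 1.0
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_finetuning_never_collapses_easy_fixture(self, two_blob_features,
                                                     small_spec, quick_config):
        """DEC/IDEC must stay within 5 points of the k-means initialization
        on trivially separable data (guard against divergence)."""
        X, y = two_blob_features
        kmeans_acc = match_accuracy(
            deep_ae_sort(X, small_spec, quick_config, K=2).labels, y
        ).accuracy
        for train in (train_dec, train_idec):
            acc = match_accuracy(train(X, small_spec, quick_config, K=2).labels,
                                 y).accuracy
            assert acc >= kmeans_acc - 0.05


class TestEnsemble:
    def test_single_member_rejected(self, quick_config):
        with pytest.raises(ValueError):
            ae_ensemble_sort(np.zeros((50, 63)), n_members=1, config=quick_config)

    def test_perfect_point_clusters(self, quick_config):
        rng = np.random.default_rng(2)
        centers = rng.normal(0, 5, size=(3, 63))
        X = np.repeat(centers, 40, axis=0) + rng.normal(0, 0.01, (120, 63))
        y = np.repeat(np.arange(3), 40)
        result = ae_ensemble_sort(X, n_members=3, config=quick_config, K=3)
        assert match_accuracy(result.labels, y).accuracy == 1.0
        assert len(result.history["members"]) == 3
        assert all("final_loss" in m for m in result.history["members"])


class TestOverclusterArtifactFilter:
    def test_empty_noise_ids_keep_everything(self, two_blob_features,
                                             small_spec, quick_config):
        X, _ = two_blob_features
        result = overcluster_artifact_filter(
            X, K_over=20, noise_class_ids=set(),
            sorter=lambda f, config=None, K=20: deep_ae_sort(
                f, small_spec, quick_config, K=K),
        )
        assert result.keep_mask.all()
        assert result.class_mean_features.shape == (20, 63)

    def test_invalid_noise_class_rejected(self, two_blob_features):
        X, _ = two_blob_features
        with pytest.raises(ValueError):
            overcluster_artifact_filter(X, K_over=20, noise_class_ids={25})

    def test_square_pulse_artifacts_isolated_and_removed(self, small_spec,
                                                         quick_config):
        rng = np.random.default_rng(7)
        spikes = rng.normal(0, 0.5, size=(600, 63))
        spikes[:300] += 4.0  # two "real" units
        artifacts = np.zeros((60, 63))
        artifacts[:, 10:40] = 12.0  # square pulses
        artifacts += rng.normal(0, 0.1, artifacts.shape)
        X = np.vstack([spikes, artifacts])
        is_artifact = np.arange(len(X)) >= 600

        def sorter(f, config=None, K=20):
            return deep_ae_sort(f, small_spec, quick_config, K=K)

        probe = overcluster_artifact_filter(X, K_over=20, sorter=sorter)
        assert len(np.unique(probe.labels)) <= 20
        counts = np.bincount(probe.labels[is_artifact], minlength=20)
        noise_class = int(np.argmax(counts))
        assert counts[noise_class] >= 0.9 * len(artifacts)
        result = overcluster_artifact_filter(X, K_over=20,
                                             noise_class_ids={noise_class},
                                             sorter=sorter)
        removed = ~result.keep_mask
        assert removed[is_artifact].mean() >= 0.9


class TestPermutationInvariance:
    def test_accuracy_invariant_under_label_permutation(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 5, 500)
        pred = rng.integers(0, 5, 500)
        base = match_accuracy(pred, true).accuracy
        perm = rng.permutation(5)
        assert match_accuracy(perm[pred], true).accuracy == base
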