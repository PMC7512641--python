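"""Sparse autoencoders, softmax head, stack training and weight diagnostics."""

import numpy as np
import pytest

from eegsae.features import FEATURES_PER_CHANNEL
from eegsae.stack import (
    ClassPosterior,
    FeatureScaler,
    SoftmaxConfig,
    SparseAEConfig,
    SparseAutoencoder,
    SoftmaxHead,
    electrode_sensitivity,
    fine_tune,
    load_stack,
    predict,
    save_stack,
    train_softmax,
    train_sparse_autoencoder,
    train_stack,
)


class TestScaler:
    def test_minmax_maps_training_range_to_unit(self):
        X = np.array([[2.0], [4.0], [6.0]])
        s = FeatureScaler.fit(X)
        assert s.transform(X).ravel() == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_maps_to_half(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        s = FeatureScaler.fit(X)
        out = s.transform(X)
        assert out[:, 0] == pytest.approx([0.5, 0.5, 0.5])

    def test_out_of_range_values_clipped(self):
        s = FeatureScaler.fit(np.array([[0.0], [10.0]]))
        out = s.transform(np.array([[-5.0], [15.0]]))
        assert out.ravel() == pytest.approx([0.0, 1.0])


class TestSparseAutoencoder:
    def test_identical_seed_and_data_identical_weights(self, rng):
        X = rng.uniform(size=(30, 12))
        cfg = SparseAEConfig(hidden_size=6, max_iterations=50, seed=3)
        a = train_sparse_autoencoder(X, cfg)
        b = train_sparse_autoencoder(X, cfg)
        assert np.array_equal(a.W_enc, b.W_enc)
        assert np.array_equal(a.W_dec, b.W_dec)

    def test_cost_decreases_over_training(self, rng):
        X = rng.uniform(size=(40, 10))
        ae = train_sparse_autoencoder(X, SparseAEConfig(hidden_size=5, max_iterations=100))
        assert ae.history[-1] <= ae.history[0]

    def test_sparsity_penalty_controls_mean_activation(self, rng):
        """Strong beta with rho=0.05 pins the mean hidden activation near rho."""
        X = rng.uniform(size=(60, 16))
        cfg = SparseAEConfig(hidden_size=8, sparsity_weight=5.0, sparsity_target=0.05,
                             max_iterations=300, seed=0)
        ae = train_sparse_autoencoder(X, cfg)
        rho_hat = ae.encode(X).mean()
        assert 0.01 <= rho_hat <= 0.15

    def test_increasing_beta_weakly_decreases_activation(self, rng):
        X = rng.uniform(size=(60, 16))
        rhos = []
        for beta in (0.0, 1.0, 10.0):
            cfg = SparseAEConfig(hidden_size=8, sparsity_weight=beta,
                                 max_iterations=200, seed=1)
            rhos.append(train_sparse_autoencoder(X, cfg).encode(X).mean())
        assert rhos[2] <= rhos[1] <= rhos[0] + 1e-6

    def test_overcomplete_ae_memorizes_tiny_set(self, rng):
        X = rng.uniform(0.2, 0.8, size=(10, 6))
        cfg = SparseAEConfig(hidden_size=24, weight_decay=0.0, sparsity_weight=0.0,
                             max_iterations=2000, seed=0)
        ae = train_sparse_autoencoder(X, cfg)
        mse = np.mean((ae.reconstruct(X) - X) ** 2)
        assert mse < 1e-3

    def test_encode_dimensions_chain(self, rng):
        X = rng.uniform(size=(320, 228))
        ae1 = train_sparse_autoencoder(X, SparseAEConfig(hidden_size=50, max_iterations=3))
        H1 = ae1.encode(X)
        assert H1.shape == (320, 50)
        ae2 = train_sparse_autoencoder(H1, SparseAEConfig(hidden_size=20, max_iterations=3))
        assert ae2.encode(H1).shape == (320, 20)
        assert np.all((H1 > 0) & (H1 < 1))

    def test_zero_weight_encoder_outputs_half(self):
        ae = SparseAutoencoder(W_enc=np.zeros((4, 6)), b_enc=np.zeros(4),
                               W_dec=np.zeros((6, 4)), b_dec=np.zeros(6),
                               config=SparseAEConfig(hidden_size=4))
        assert np.all(ae.encode(np.ones((3, 6))) == 0.5)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.uniform(size=(10, 6))
        ae = train_sparse_autoencoder(X, SparseAEConfig(hidden_size=3, max_iterations=5))
        with pytest.raises(ValueError, match="features"):
            ae.encode(rng.uniform(size=(4, 9)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sparsity_target"):
            SparseAEConfig(hidden_size=5, sparsity_target=1.0)
        with pytest.raises(ValueError, match="hidden_size"):
            SparseAEConfig(hidden_size=0)


class TestSoftmaxAndPredict:
    def test_posteriors_sum_to_one(self, rng):
        H = rng.uniform(size=(30, 8))
        y = np.array(["CNT", "PNES"] * 15)
        head = train_softmax(H, y)
        p = head.proba(H)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_equal_logits_give_half_half(self):
        head = SoftmaxHead(W=np.zeros((2, 4)), b=np.zeros(2), config=SoftmaxConfig())
        p = head.proba(np.ones((1, 4)))
        assert p[0] == pytest.approx([0.5, 0.5])

    def test_ten_unit_logit_gap_saturates(self):
        head = SoftmaxHead(W=np.zeros((2, 1)), b=np.array([0.0, 10.0]),
                           config=SoftmaxConfig())
        p = head.proba(np.zeros((1, 1)))
        assert p[0, 1] > 0.9999

    def test_single_class_training_rejected(self, rng):
        H = rng.uniform(size=(10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_softmax(H, np.array(["CNT"] * 10))


class TestTrainStack:
    def test_dims_recorded_in_provenance(self, trained_stack):
        assert tuple(trained_stack.provenance["dims"]) == (228, 50, 20, 2)

    def test_training_accuracy_on_separable_cohort(self, small_features, trained_stack):
        acc = np.mean(trained_stack.predict_labels(small_features.X) == small_features.y)
        assert acc >= 0.95

    def test_unsupervised_stages_are_label_blind(self, small_features, rng):
        """Shuffling labels must leave AE weights bitwise identical."""
        cfg1 = SparseAEConfig(hidden_size=10, max_iterations=30, seed=5)
        cfg2 = SparseAEConfig(hidden_size=4, max_iterations=30, seed=6)
        y = small_features.y
        y_shuf = rng.permutation(y)
        while len(np.unique(y_shuf)) < 2:  # pragma: no cover
            y_shuf = rng.permutation(y)
        a = train_stack(small_features.X, y, cfg1, cfg2)
        b = train_stack(small_features.X, y_shuf, cfg1, cfg2)
        assert np.array_equal(a.ae1.W_enc, b.ae1.W_enc)
        assert np.array_equal(a.ae2.W_enc, b.ae2.W_enc)

    def test_stack_determinism(self, small_features):
        cfg1 = SparseAEConfig(hidden_size=10, max_iterations=20, seed=5)
        cfg2 = SparseAEConfig(hidden_size=4, max_iterations=20, seed=6)
        a = train_stack(small_features.X, small_features.y, cfg1, cfg2)
        b = train_stack(small_features.X, small_features.y, cfg1, cfg2)
        assert np.array_equal(a.softmax.W, b.softmax.W)

    def test_predict_returns_normalized_posterior(self, trained_stack, small_features):
        post = predict(trained_stack, small_features.X[0])
        assert isinstance(post, ClassPosterior)
        assert post.p_cnt + post.p_pnes == pytest.approx(1.0, abs=1e-9)

    def test_scaler_fitted_on_training_rows_only(self, small_features):
        X, y = small_features.X, small_features.y
        stack = train_stack(X[:-1], y[:-1],
                            SparseAEConfig(hidden_size=8, max_iterations=5),
                            SparseAEConfig(hidden_size=4, max_iterations=5))
        refit = FeatureScaler.fit(X[:-1])
        assert np.array_equal(stack.scaler.min_, refit.min_)
        assert np.array_equal(stack.scaler.range_, refit.range_)


class TestFineTune:
    def test_zero_epochs_is_identity(self, trained_stack, small_features):
        out = fine_tune(trained_stack, small_features, epochs=0)
        assert np.array_equal(out.ae1.W_enc, trained_stack.ae1.W_enc)
        assert out.fine_tuned is False

    def test_loss_non_increasing_and_original_preserved(self, trained_stack, small_features):
        before = trained_stack.ae1.W_enc.copy()
        out = fine_tune(trained_stack, small_features, epochs=20)
        assert out.fine_tuned is True
        ft = out.provenance["fine_tune"]
        assert ft["loss_end"] <= ft["loss_start"] + 1e-12
        assert np.array_equal(trained_stack.ae1.W_enc, before)


class TestElectrodeSensitivity:
    def _stack_with_w1(self, W1):
        h1, d = W1.shape
        ae1 = SparseAutoencoder(W1, np.zeros(h1), np.zeros((d, h1)), np.zeros(d),
                                SparseAEConfig(hidden_size=h1))
        ae2 = SparseAutoencoder(np.ones((4, h1)), np.zeros(4), np.zeros((h1, 4)),
                                np.zeros(h1), SparseAEConfig(hidden_size=4))
        head = SoftmaxHead(W=np.ones((2, 4)), b=np.zeros(2), config=SoftmaxConfig())
        from eegsae.stack import EncoderStack
        return EncoderStack(scaler=FeatureScaler(np.zeros(d), np.ones(d)),
                            ae1=ae1, ae2=ae2, softmax=head)

    def test_duplicate_channels_get_equal_scores(self, rng):
        d = 19 * FEATURES_PER_CHANNEL
        W1 = rng.normal(size=(6, d))
        W1[:, 12:24] = W1[:, 0:12]  # channel 1 copies channel 0
        scores, _ = electrode_sensitivity(self._stack_with_w1(W1))
        assert scores[0] == pytest.approx(scores[1])

    def test_zeroed_channel_scores_zero(self, rng):
        d = 19 * FEATURES_PER_CHANNEL
        W1 = rng.normal(size=(6, d))
        W1[:, 5 * 12 : 6 * 12] = 0.0
        scores, ranking = electrode_sensitivity(self._stack_with_w1(W1))
        assert scores[5] == 0.0
        assert ranking[-1] == "C4"  # channel index 5

    def test_scores_normalized(self, trained_stack):
        scores, ranking = electrode_sensitivity(trained_stack)
        assert scores.sum() == pytest.approx(1.0)
        assert len(ranking) == 19


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, trained_stack, small_features):
        path = tmp_path / "model.npz"
        save_stack(trained_stack, path)
        back = load_stack(path)
        assert np.array_equal(back.predict_proba(small_features.X),
                              trained_stack.predict_proba(small_features.X))
        assert tuple(back.provenance["dims"]) == (228, 50, 20, 2)
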