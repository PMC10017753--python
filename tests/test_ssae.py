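"""Semi-supervised autoencoder: losses, gradients, training behaviour, and
the cross-validation protocol."""

import dataclasses

import numpy as np
import pytest

from connsae.ssae import (AEConfig, binary_cross_entropy_loss, combined_loss,
                          cross_validate_ssae, encode, inject_gaussian_noise,
                          mse_reconstruction_loss, pca_svm_baseline, predict,
                          train_ssae, _backward, _forward, _init_params)


SMALL = AEConfig(encoder_sizes=(20, 12, 6), decoder_sizes=(6, 12, 20),
                 classifier_sizes=(6, 4, 1))


def blobs(rng, n=60, n_features=20, n_informative=6, d=4.0):
    """Two well-separated gaussian blobs, scaled into [0, 1]."""
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, n_features))
    X[y == 1, :n_informative] += d
    X = (X - X.min(0)) / (X.max(0) - X.min(0))
    return X, y.astype(float)


class TestLosses:
    def test_perfect_reconstruction_is_zero(self, rng):
        X = rng.random((5, 7))
        assert mse_reconstruction_loss(X, X) == 0.0

    def test_single_subject_two_features(self):
        X = np.array([[0.5, 0.5]])
        Xr = np.array([[0.6, 0.8]])
        assert mse_reconstruction_loss(X, Xr) == pytest.approx(0.05)

    def test_mse_equals_double_loop(self, rng):
        X, Xr = rng.random((8, 11)), rng.random((8, 11))
        brute = np.mean([np.mean([(Xr[i, j] - X[i, j]) ** 2
                                  for j in range(11)]) for i in range(8)])
        assert mse_reconstruction_loss(X, Xr) == pytest.approx(brute, abs=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_reconstruction_loss(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_bce_coin_flip_is_ln2(self):
        assert binary_cross_entropy_loss([1.0], [0.5]) == pytest.approx(np.log(2))

    def test_bce_confident_correct_near_zero(self):
        assert binary_cross_entropy_loss([1.0, 0.0], [1.0, 0.0]) < 1e-6

    def test_bce_equals_hand_sum(self, rng):
        y = rng.integers(0, 2, size=12).astype(float)
        p = rng.uniform(0.05, 0.95, size=12)
        brute = -np.mean([yy * np.log(pp) + (1 - yy) * np.log(1 - pp)
                          for yy, pp in zip(y, p)])
        assert binary_cross_entropy_loss(y, p) == pytest.approx(brute, abs=1e-14)

    def test_combined_loss_weights(self):
        assert combined_loss(0.1, 0.2) == pytest.approx(0.13, abs=1e-15)
        assert combined_loss(0.0, 0.0) == 0.0
        assert combined_loss(1.0, 0.0) == pytest.approx(0.7)

    def test_combined_loss_identity_on_random_batches(self, rng):
        for _ in range(20):
            mse, bce = rng.random(2)
            assert abs(combined_loss(mse, bce) - (0.7 * mse + 0.3 * bce)) < 1e-12


class TestNoise:
    def test_zero_std_or_fraction_is_identity(self, rng):
        X = rng.random((10, 10))
        assert np.array_equal(inject_gaussian_noise(X, std=0.0, seed=1), X)
        assert np.array_equal(inject_gaussian_noise(X, fraction=0.0, seed=1), X)

    def test_perturbed_share_concentrates(self, rng):
        X = np.zeros((200, 500))
        Xn = inject_gaussian_noise(X, fraction=0.2, std=0.02, seed=0)
        share = (Xn != 0).mean()
        assert abs(share - 0.2) < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            inject_gaussian_noise(np.zeros((2, 2)), fraction=1.5)
        with pytest.raises(ValueError):
            inject_gaussian_noise(np.zeros((2, 2)), std=-1.0)


class TestConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AEConfig(decoder_loss_weight=0.6, classifier_loss_weight=0.3)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            AEConfig(encoder_sizes=(60, 40, 20), decoder_sizes=(10, 40, 60))
        with pytest.raises(ValueError):
            AEConfig(classifier_sizes=(20, 20, 2))

    def test_default_architecture(self):
        cfg = AEConfig()
        assert cfg.input_dim == 60 and cfg.latent_dim == 20


def test_backprop_matches_finite_differences(rng):
    """Analytic gradients of the composite loss agree with central finite
    differences for every parameter tensor."""
    cfg = AEConfig(encoder_sizes=(6, 5, 3), decoder_sizes=(3, 5, 6),
                   classifier_sizes=(3, 2, 1))
    params = _init_params(cfg, rng)
    X = rng.random((7, 6))
    y = rng.integers(0, 2, size=7).astype(float)

    def loss_fn(ps):
        acts = _forward(ps, X)
        return combined_loss(mse_reconstruction_loss(X, acts["xr"]),
                             binary_cross_entropy_loss(y, acts["p"]))

    acts = _forward(params, X)
    grads = _backward(params, X, X, y, acts, 0.7, 0.3)
    eps = 1e-6
    for key in params:
        num = np.zeros_like(params[key])
        it = np.nditer(params[key], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = params[key][idx]
            params[key][idx] = orig + eps
            up = loss_fn(params)
            params[key][idx] = orig - eps
            down = loss_fn(params)
            params[key][idx] = orig
            num[idx] = (up - down) / (2 * eps)
        assert np.allclose(grads[key], num, atol=1e-8), key


class TestTraining:
    def test_separable_data_stops_on_accuracy(self):
        stops = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X, y = blobs(rng)
            model = train_ssae(X, y, dataclasses.replace(SMALL, seed=seed))
            stops += model.stop_reason == "accuracy"
        assert stops >= 0.9 * n_seeds

    def test_loss_decreases(self, rng):
        X, y = blobs(rng)
        model = train_ssae(X, y, SMALL)
        assert model.history["loss"][-1] <= model.history["loss"][0]

    def test_same_seed_identical_parameters(self, rng):
        X, y = blobs(rng)
        a = train_ssae(X, y, SMALL)
        b = train_ssae(X, y, SMALL)
        assert a.checksum() == b.checksum()
        assert a.n_epochs == b.n_epochs

    def test_epoch_budget_respected(self, rng):
        X, y = blobs(rng)
        cfg = dataclasses.replace(SMALL, max_epochs=5)
        model = train_ssae(X, y, cfg)
        assert model.n_epochs <= 5 and model.stop_reason in ("accuracy",
                                                             "max_epochs")


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X, y = blobs(rng)
    return train_ssae(X, y, SMALL), X, y


class TestPredictEncode:

    def test_latent_dimension(self, fitted):
        model, X, _ = fitted
        assert encode(model, X).shape == (len(X), SMALL.latent_dim)

    def test_probabilities_in_open_interval(self, fitted):
        model, X, _ = fitted
        p = predict(model, X)
        assert np.all((p > 0) & (p < 1))

    def test_converged_fit_is_accurate_on_train(self, fitted):
        model, X, y = fitted
        if model.stop_reason == "accuracy":
            acc = (((predict(model, X) >= 0.5).astype(float)) == y).mean()
            assert acc > 0.95

    def test_duplicated_row_identical_output(self, fitted):
        model, X, _ = fitted
        two = np.vstack([X[0], X[0]])
        p = predict(model, two)
        assert p[0] == p[1]

    def test_feature_mismatch_rejected(self, fitted):
        model, X, _ = fitted
        with pytest.raises(ValueError):
            predict(model, X[:, :-1])

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        model, X, _ = fitted
        path = tmp_path / "model.json"
        model.save(path)
        from connsae.ssae import TrainedSSAE
        loaded = TrainedSSAE.load(path)
        assert loaded.config == model.config
        assert np.allclose(predict(loaded, X), predict(model, X))
        assert loaded.stop_reason == model.stop_reason


class TestCrossValidation:
    def test_fold_sizes_partition_105(self):
        rng = np.random.default_rng(1)
        X, y = blobs(rng, n=106, n_features=20)
        X, y = X[:105], y[:105]
        cfg = dataclasses.replace(SMALL, max_epochs=3)
        cv = cross_validate_ssae(X, y, cfg, k=5)
        sizes = [len(va) for _, va in cv.fold_indices]
        assert sizes == [21] * 5

    def test_folds_disjoint_exhaustive_stratified(self):
        rng = np.random.default_rng(2)
        X, y = blobs(rng, n=60)
        cfg = dataclasses.replace(SMALL, max_epochs=3)
        cv = cross_validate_ssae(X, y, cfg, k=5)
        all_val = np.concatenate([va for _, va in cv.fold_indices])
        assert sorted(all_val) == list(range(60))
        for _, va in cv.fold_indices:
            frac = y[va].mean()
            assert abs(frac - 0.5) <= 1 / len(va)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = blobs(rng, n=40)
        cfg = dataclasses.replace(SMALL, max_epochs=10)
        a = cross_validate_ssae(X, y, cfg, k=4, seed=9)
        b = cross_validate_ssae(X, y, cfg, k=4, seed=9)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.aucs, b.aucs)

    def test_too_small_class_rejected(self):
        X = np.random.default_rng(0).random((6, 20))
        y = np.array([0, 0, 0, 0, 0, 1.0])
        with pytest.raises(ValueError):
            cross_validate_ssae(X, y, SMALL, k=5)

    def test_in_fold_selection_from_wide_input(self):
        """685-feature input triggers per-fold reduction to the encoder width."""
        rng = np.random.default_rng(4)
        y = np.repeat([0.0, 1.0], 20)
        X = rng.standard_normal((40, 100))
        X[y == 1, :5] += 3.0
        cfg = dataclasses.replace(SMALL, max_epochs=5)
        cv = cross_validate_ssae(X, y, cfg, k=4, n_select=20)
        for sel in cv.selections:
            assert sel is not None and len(sel.selected) == 20


class TestBaseline:
    def test_same_fold_assignments_as_ssae(self):
        rng = np.random.default_rng(5)
        X, y = blobs(rng, n=50)
        cfg = dataclasses.replace(SMALL, max_epochs=3)
        cv = cross_validate_ssae(X, y, cfg, k=5, seed=13)
        bl = pca_svm_baseline(X, y, k=5, seed=13)
        assert np.array_equal(cv.fold_assignments, bl.fold_assignments)

    def test_separable_data_high_accuracy(self):
        rng = np.random.default_rng(6)
        X, y = blobs(rng, n=80)
        bl = pca_svm_baseline(X, y, k=5, seed=0)
        assert bl.accuracy_mean >= 0.9
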