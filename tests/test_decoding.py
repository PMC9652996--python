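"""Decoding: features, PCA, Fisher scores, shrinkage LDA, cross-validation."""

import numpy as np
import pytest
from scipy import linalg, signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from errp_exo import decoding as dec
from errp_exo.preprocess import EpochSet


def _epochs(data, labels, rate=1000.0, modality="eeg", window=(0.0, 1.0),
            channels=None):
    n, c, s = data.shape
    return EpochSet(
        data=data.astype(np.float32), labels=np.asarray(labels, dtype=np.int8),
        modality=modality, window=window, rate=rate,
        channel_names=tuple(channels or dec.EEG_FEATURE_CHANNELS[:c]),
        schemes=np.array(["gravity"] * n, dtype=object),
        block_error_rates=np.full(n, 0.3),
        event_indices=np.arange(n),
    )


def _gaussian_classes(n_per_class, d, sep, rng, cov=None):
    cov = np.eye(d) if cov is None else cov
    L = np.linalg.cholesky(cov)
    mu = np.zeros(d)
    mu[0] = sep
    X0 = rng.standard_normal((n_per_class, d)) @ L.T
    X1 = rng.standard_normal((n_per_class, d)) @ L.T + mu
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return X, y


class TestFeatures:
    def test_eeg_feature_layout_1375(self):
        rng = np.random.default_rng(0)
        eps = _epochs(rng.standard_normal((6, 11, 1000)), [0, 1] * 3)
        fm = dec.extract_features(eps)
        assert fm.X.shape == (6, 11 * 125)
        assert len(fm.feature_map) == 1375
        assert len(set(fm.feature_map)) == 1375  # unique (channel, time) per column
        with pytest.raises(ValueError):
            dec.extract_features(eps, channels=("Oz",))

    def test_temporal_binning_approx_200(self):
        rng = np.random.default_rng(1)
        eps = _epochs(rng.standard_normal((4, 11, 1000)), [0, 1, 0, 1])
        fm = dec.extract_features(eps, bin_ms=55.0)
        assert fm.X.shape[1] == 11 * 18  # 198 features

    def test_decimation_preserves_slow_tone(self):
        t = np.arange(1000) / 1000.0
        tone = np.sin(2 * np.pi * 5.0 * t)
        eps = _epochs(np.tile(tone, (4, 11, 1)), [0, 1, 0, 1])
        fm = dec.extract_features(eps)
        per_trial = fm.X[0].reshape(11, 125)
        gain = np.max(np.abs(per_trial[0, 10:-10])) / np.max(np.abs(tone))
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_emg_and_kinematics_native_rate(self):
        rng = np.random.default_rng(2)
        emg = _epochs(rng.standard_normal((4, 2, 378)), [0, 1, 0, 1],
                      rate=222.2, modality="emg", window=(-0.2, 1.5),
                      channels=("biceps", "triceps"))
        assert dec.extract_features(emg).X.shape == (4, 2 * 378)
        kin = _epochs(rng.standard_normal((4, 1, 170)), [0, 1, 0, 1],
                      rate=100.0, modality="kinematics", window=(-0.2, 1.5),
                      channels=("v",))
        assert dec.extract_features(kin).X.shape == (4, 170)


class TestPca:
    def test_planar_data_two_components(self):
        rng = np.random.default_rng(3)
        basis = rng.standard_normal((2, 20))
        X = rng.standard_normal((50, 2)) @ basis
        Z, pca = dec.pca_reduce(X, 0.999)
        assert pca.n_components_ == 2
        assert np.allclose(pca.transform(X.mean(0, keepdims=True)), 0.0, atol=1e-9)

    def test_reconstruction_error_equals_discarded_eigenvalues(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 12)) * np.linspace(3, 0.1, 12)
        Z, pca = dec.pca_reduce(X, 0.90)
        Xc = X - X.mean(0)
        recon = Z @ pca.components_
        sse = np.sum((Xc - recon) ** 2) / (len(X) - 1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert sse == pytest.approx(eigvals[pca.n_components_:].sum(), rel=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            dec.pca_reduce(np.ones((10, 5)))


class TestFisher:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 7))
        y = (rng.random(80) < 0.4).astype(int)
        scores = dec.fisher_scores(X, y)
        for f in range(7):
            a, b = X[y == 0, f], X[y == 1, f]
            expected = (a.mean() - b.mean()) ** 2 / (a.var() + b.var())
            assert scores[f] == pytest.approx(expected)

    def test_identical_and_separating_features(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 3))
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        X[:, 2] = y * 10 + 0.01 * rng.standard_normal(100)  # near-perfect separator
        scores = dec.fisher_scores(X, y)
        assert np.argmax(scores) == 2
        assert scores[0] < 0.2 and scores[1] < 0.2
        with pytest.raises(ValueError):
            dec.fisher_scores(X, np.zeros(100, int))


class TestRlda:
    def test_lambda_zero_equals_classical_lda(self):
        """Generalized-eigenvector oracle + sklearn agreement at lambda=0."""
        rng = np.random.default_rng(7)
        cov = linalg.toeplitz(0.5 ** np.arange(5))
        X, y = _gaussian_classes(100, 5, 2.0, rng, cov)
        model = dec.rlda_fit(X, y, shrinkage=0.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Sw = ((X[y == 0] - mu0).T @ (X[y == 0] - mu0)
              + (X[y == 1] - mu1).T @ (X[y == 1] - mu1)) / len(X)
        w_oracle = np.linalg.solve(Sw, mu1 - mu0)
        cos = w_oracle @ model.weights / (np.linalg.norm(w_oracle) * np.linalg.norm(model.weights))
        assert abs(cos - 1.0) < 1e-8
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        assert np.array_equal(sk.predict(X), dec.rlda_predict(model, X))

    def test_lambda_one_is_nearest_class_mean(self):
        rng = np.random.default_rng(8)
        X, y = _gaussian_classes(60, 6, 1.5, rng)
        model = dec.rlda_fit(X, y, shrinkage=1.0)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        cos = diff @ model.weights / (np.linalg.norm(diff) * np.linalg.norm(model.weights))
        assert abs(cos - 1.0) < 1e-10

    def test_auto_shrinkage_matches_sklearn_lsqr(self):
        rng = np.random.default_rng(9)
        cov = linalg.toeplitz(0.7 ** np.arange(30))
        X, y = _gaussian_classes(40, 30, 1.0, rng, cov)
        model = dec.rlda_fit(X, y)
        assert 0.0 < model.shrinkage < 1.0
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                        priors=[0.5, 0.5]).fit(X, y)
        agreement = np.mean(sk.predict(X) == dec.rlda_predict(model, X))
        # same shrinkage family; small covariance-estimator differences allowed
        assert agreement > 0.9

    def test_separated_gaussians_holdout_accuracy(self):
        rng = np.random.default_rng(10)
        X, y = _gaussian_classes(200, 10, 4.0, rng)
        Xt, yt = _gaussian_classes(200, 10, 4.0, rng)
        model = dec.rlda_fit(X, y)
        assert np.mean(dec.rlda_predict(model, Xt) == yt) > 0.95

    def test_tie_break_and_dimension_guardrails(self):
        rng = np.random.default_rng(11)
        X, y = _gaussian_classes(20, 3, 2.0, rng)
        model = dec.rlda_fit(X, y, shrinkage=0.1)
        on_plane = np.linalg.lstsq(model.weights[None, :], [-model.bias], rcond=None)[0]
        assert dec.rlda_predict(model, on_plane[None, :])[0] == dec.LABEL_NON_ERROR
        with pytest.raises(ValueError):
            dec.rlda_predict(model, X[:, :2])
        with pytest.raises(ValueError):
            dec.rlda_fit(X[:3], np.array([0, 1, 1]))


class TestCrossValidation:
    def test_separable_fixture_perfect_and_deterministic(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((60, 2, 50)).astype(np.float32)
        labels = np.r_[np.zeros(40, int), np.ones(20, int)]
        data[labels == 1] += 5.0
        eps = _epochs(data, labels, rate=100.0, modality="kinematics",
                      window=(0.0, 0.5), channels=("a", "b"))
        r1 = dec.run_cv(eps, n_folds=5, n_repeats=2, seed=3)
        assert r1.mean_accuracy == 100.0
        assert r1.confusion.sum() == 60 * 2
        r2 = dec.run_cv(eps, n_folds=5, n_repeats=2, seed=3)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_label_shuffle_gives_chance(self):
        """Leak detector: random labels after feature extraction -> chance."""
        rng = np.random.default_rng(13)
        data = rng.standard_normal((200, 3, 40)).astype(np.float32)
        labels = rng.integers(0, 2, 200)
        eps = _epochs(data, labels, rate=100.0, modality="kinematics",
                      window=(0.0, 0.4), channels=("a", "b", "c"))
        res = dec.run_cv(eps, n_folds=10, n_repeats=2, seed=5)
        half_width = 196.0 * np.sqrt(0.25 / 200)
        assert abs(res.mean_accuracy - 50.0) < half_width

    def test_insufficient_trials_rejected(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((12, 1, 10)).astype(np.float32)
        eps = _epochs(data, [0] * 8 + [1] * 4, rate=100.0, modality="kinematics",
                      window=(0.0, 0.1), channels=("a",))
        with pytest.raises(ValueError):
            dec.run_cv(eps, n_folds=10)


def test_fisher_preselection_keeps_separable_fixture_perfect():
    rng = np.random.default_rng(15)
    data = rng.standard_normal((60, 2, 50)).astype(np.float32)
    labels = np.r_[np.zeros(40, int), np.ones(20, int)]
    data[labels == 1, :, 10:20] += 4.0
    eps = _epochs(data, labels, rate=100.0, modality="kinematics",
                  window=(0.0, 0.5), channels=("a", "b"))
    res = dec.run_cv(eps, n_folds=5, n_repeats=1, seed=4, fisher_top_k=20)
    assert res.mean_accuracy == 100.0
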