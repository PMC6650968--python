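import numpy as np
import pytest
from scipy import stats

from thermoface.recognition import (
    CLASSIFIER_KINDS,
    apply_normalization,
    confusion_and_metrics,
    cross_validate,
    fit_classifier,
    fit_normalization,
    fit_pca,
    load_models,
    predict,
    project,
    save_models,
    stratified_folds,
)
from thermoface.synthetic_fixtures import generate_feature_dataset


class TestNormalization:
    def test_training_data_standardized(self, rng):
        x = rng.normal(5, 3, (100, 10))
        model = fit_normalization(x)
        z = apply_normalization(model, x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_maps_to_zero(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        z = apply_normalization(fit_normalization(x), x)
        assert np.all(z[:, 1] == 0)

    def test_validation_at_training_mean_is_zero(self, rng):
        x = rng.normal(size=(30, 4))
        model = fit_normalization(x)
        z = apply_normalization(model, x.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(z, 0, atol=1e-12)


class TestPCA:
    def test_components_orthonormal(self, rng):
        model = fit_pca(rng.normal(size=(50, 20)), 10)
        np.testing.assert_allclose(
            model.components.T @ model.components, np.eye(10), atol=1e-10
        )

    def test_rank_two_data_reconstructed(self, rng):
        basis = rng.normal(size=(2, 15))
        coords = rng.normal(size=(40, 2))
        x = coords @ basis + rng.normal(size=15)
        model = fit_pca(x, 2)
        proj = project(model, x)
        recon = proj @ model.components.T + model.mean
        np.testing.assert_allclose(recon, x, atol=1e-9)

    def test_explained_variance_non_increasing(self, rng):
        model = fit_pca(rng.normal(size=(60, 25)), 20)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_q_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 5)), 10)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.normal(size=(80, 12))
        ours = fit_pca(x, 5)
        sk = SkPCA(n_components=5, svd_solver="full").fit(x)
        np.testing.assert_allclose(
            np.abs(ours.components.T), np.abs(sk.components_), atol=1e-8
        )
        np.testing.assert_allclose(ours.explained_variance, sk.explained_variance_, atol=1e-8)


class TestClassifiers:
    def test_lda_boundary_at_zero_symmetric_1d(self, rng):
        x = np.concatenate([rng.normal(-5, 1, 200), rng.normal(5, 1, 200)])[:, None]
        y = np.array([1] * 200 + [2] * 200)
        model = fit_classifier("lda_full", x, y)
        assert predict(model, np.array([[-0.2]]))[0] == 1
        assert predict(model, np.array([[0.2]]))[0] == 2

    @pytest.mark.parametrize("kind", [k for k in CLASSIFIER_KINDS if k != "linear_svm"])
    def test_separated_clouds_train_accuracy_100(self, kind, rng):
        mean = np.zeros(10)
        mean2 = np.full(10, 10 / np.sqrt(10))  # separation 10 sigma
        x = np.vstack([rng.normal(mean, 1, (100, 10)), rng.normal(mean2, 1, (100, 10))])
        y = np.array([1] * 100 + [2] * 100)
        model = fit_classifier(kind, x, y)
        assert np.mean(predict(model, x) == y) == 1.0

    def test_lda_diag_matches_full_when_cov_diagonal_by_construction(self):
        # two interleaved points per quadrant: pooled covariance exactly diagonal
        x = np.array(
            [[-1.0, -2.0], [1.0, 2.0], [-1.0, 2.0], [1.0, -2.0],
             [9.0, 8.0], [11.0, 12.0], [9.0, 12.0], [11.0, 8.0]]
        )
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        full = fit_classifier("lda_full", x, y)
        diag = fit_classifier("lda_diag", x, y)
        np.testing.assert_allclose(full.pooled_cov, diag.pooled_cov, atol=1e-12)
        grid = np.array([[a, b] for a in np.linspace(-5, 15, 9) for b in np.linspace(-5, 15, 9)])
        np.testing.assert_array_equal(predict(full, grid), predict(diag, grid))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_classifier("lda_full", rng.normal(size=(10, 3)), np.ones(10))

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_classifier("forest", rng.normal(size=(10, 3)), np.array([1] * 5 + [2] * 5))

    def test_lda_matches_sklearn_cross_check(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x, y = generate_feature_dataset(40, n_classes=3, separation=3.0, d=8, seed=3)
        ours = fit_classifier("lda_full", x, y)
        sk = LinearDiscriminantAnalysis().fit(x, y)
        xt, _ = generate_feature_dataset(20, n_classes=3, separation=3.0, d=8, seed=4)
        agree = np.mean(predict(ours, xt) == sk.predict(xt))
        assert agree >= 0.97

    def test_qda_matches_sklearn_cross_check(self, rng):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        x, y = generate_feature_dataset(60, n_classes=3, separation=3.0, d=6, seed=5)
        ours = fit_classifier("qda_full", x, y)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(x, y)
        xt, _ = generate_feature_dataset(30, n_classes=3, separation=3.0, d=6, seed=6)
        assert np.mean(predict(ours, xt) == sk.predict(xt)) >= 0.97

    def test_closed_form_two_gaussian_posterior_1d(self):
        # equal priors, unit variance, means -2 / +2: boundary exactly at 0,
        # decision flips with the analytic posterior sign
        x = np.array([[-3.0], [-1.0], [-2.0], [1.0], [3.0], [2.0]])
        y = np.array([1, 1, 1, 2, 2, 2])
        model = fit_classifier("lda_full", x, y)
        for xv in np.linspace(-4, 4, 33):
            analytic = 1 if stats.norm.pdf(xv, -2, 1) > stats.norm.pdf(xv, 2, 1) else 2
            if abs(xv) > 1e-9:
                assert predict(model, np.array([[xv]]))[0] == analytic

    def test_mahalanobis_ignores_priors(self, rng):
        # heavily imbalanced classes: nearest-mean rule is unaffected
        x = np.vstack([rng.normal(0, 1, (190, 2)), rng.normal(6, 1, (10, 2))])
        y = np.array([1] * 190 + [2] * 10)
        model = fit_classifier("mahalanobis", x, y)
        assert predict(model, np.array([[5.5, 5.5]]))[0] == 2

    def test_linear_svm_delegates(self, rng):
        x, y = generate_feature_dataset(30, n_classes=2, separation=6.0, d=5, seed=7)
        model = fit_classifier("linear_svm", x, y)
        assert np.mean(predict(model, x) == y) >= 0.99


class TestMetrics:
    def test_perfect_predictions(self):
        res = confusion_and_metrics([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.acc == 1.0 and res.kappa == 1.0
        assert np.all(res.tpr == 1.0) and np.all(res.fpr == 0.0)

    def test_hand_worked_two_class_kappa(self):
        # confusion [[40, 10], [20, 30]]
        y_true = [1] * 50 + [2] * 50
        y_pred = [1] * 40 + [2] * 10 + [1] * 20 + [2] * 30
        res = confusion_and_metrics(y_true, y_pred, n_classes=2)
        np.testing.assert_array_equal(res.confusion, [[40, 10], [20, 30]])
        assert res.acc == pytest.approx(0.7)
        assert res.kappa == pytest.approx(0.4)
        assert res.tpr == pytest.approx([0.8, 0.6])
        assert res.fpr == pytest.approx([0.4, 0.2])

    def test_chance_predictions_kappa_near_zero(self, rng):
        y_true = rng.integers(1, 6, 20000)
        y_pred = rng.integers(1, 6, 20000)
        res = confusion_and_metrics(y_true, y_pred)
        assert abs(res.kappa) < 0.02

    def test_matches_sklearn_kappa(self, rng):
        from sklearn.metrics import cohen_kappa_score

        y_true = rng.integers(1, 6, 500)
        y_pred = np.where(rng.random(500) < 0.6, y_true, rng.integers(1, 6, 500))
        res = confusion_and_metrics(y_true, y_pred)
        assert res.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])

    def test_confusion_row_sums_are_class_counts(self, rng):
        y_true = rng.integers(1, 6, 300)
        y_pred = rng.integers(1, 6, 300)
        res = confusion_and_metrics(y_true, y_pred)
        counts = [np.sum(y_true == c) for c in res.classes]
        np.testing.assert_array_equal(res.confusion.sum(axis=1), counts)


class TestCrossValidation:
    def test_folds_disjoint_cover_stratified(self, rng):
        y = np.repeat([1, 2, 3], [30, 31, 32])
        assignment = stratified_folds(y, 3, rng)
        assert set(assignment) == {0, 1, 2}
        for c in (1, 2, 3):
            counts = np.bincount(assignment[y == c], minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_class_smaller_than_k_rejected(self, rng):
        y = np.array([1, 1, 1, 2, 2])
        with pytest.raises(ValueError):
            stratified_folds(y, 3, rng)

    def test_same_seed_reproducible(self):
        x, y = generate_feature_dataset(15, separation=2.0, d=20, seed=1)
        a = cross_validate(x, y, "lda_full", components=5, k=3, runs=2, seed=9)
        b = cross_validate(x, y, "lda_full", components=5, k=3, runs=2, seed=9)
        assert a.acc == b.acc and a.kappa == b.kappa
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_no_leak_models_independent_of_validation_labels(self, rng):
        x, y = generate_feature_dataset(12, separation=2.0, d=10, seed=2)
        assignment = stratified_folds(y, 3, np.random.default_rng(0))
        train = assignment != 0
        norm1 = fit_normalization(x[train])
        pca1 = fit_pca(apply_normalization(norm1, x[train]), 5)
        # shuffle validation labels: training-fitted models must be identical
        y2 = y.copy()
        y2[~train] = rng.permutation(y2[~train])
        norm2 = fit_normalization(x[train])
        pca2 = fit_pca(apply_normalization(norm2, x[train]), 5)
        np.testing.assert_array_equal(norm1.mean, norm2.mean)
        np.testing.assert_array_equal(pca1.components, pca2.components)

    def test_parameter_recovery_separation_five(self):
        accs = []
        for seed in range(5):
            x, y = generate_feature_dataset(40, separation=5.0, d=154, seed=seed)
            res = cross_validate(x, y, "lda_full", components=30, k=3, runs=1, seed=seed)
            accs.append(res.acc)
        assert min(accs) >= 0.95


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, rng):
        x, y = generate_feature_dataset(20, separation=4.0, d=12, seed=11)
        norm = fit_normalization(x)
        xn = apply_normalization(norm, x)
        pca = fit_pca(xn, 6)
        clf = fit_classifier("lda_full", project(pca, xn), y)
        path = tmp_path / "model.json"
        save_models(path, norm, pca, clf)
        norm2, pca2, clf2 = load_models(path)
        xt = rng.normal(size=(10, 12))
        zt = project(pca2, apply_normalization(norm2, xt))
        np.testing.assert_allclose(
            predict(clf, project(pca, apply_normalization(norm, xt))),
            predict(clf2, zt),
        )
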