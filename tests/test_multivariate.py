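"""PCA, PC-LDA, LOPO cross-validation, diagnostic metrics, learning curve."""

import math

import numpy as np
import pandas as pd
import pytest

from reimsdx.multivariate import (
    ConfusionTable,
    CVMetrics,
    PCAModel,
    PCLDAModel,
    cross_validate_lopo,
    fit_pca,
    fit_pclda,
    learning_curve,
    metrics_from_confusion,
    predict_sample,
)
from reimsdx.preprocessing import FeatureMatrix


def make_matrix(X, labels, patients=None):
    n = len(labels)
    return FeatureMatrix(
        [f"S{i}" for i in range(n)],
        patients or [f"P{i}" for i in range(n)],
        list(labels),
        np.asarray(X, dtype=float),
    )


def two_class_blobs(n_per_class=12, sep=6.0, n_dims=30, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per_class, n_dims))
    b = rng.normal(0.0, 1.0, (n_per_class, n_dims))
    b[:, 0] += sep
    X = np.vstack([a, b])
    labels = ["normal"] * n_per_class + ["cancer"] * n_per_class
    return make_matrix(np.abs(X) + 1.0, labels)


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 10)[:, None]
        direction = np.zeros((1, 4000))
        direction[0, :3] = [1.0, 2.0, 3.0]
        X = t @ direction
        model = fit_pca(X, 2)
        assert model.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-6)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (10000, 2))
        model = fit_pca(X, 2)
        assert model.explained_variance_pct[0] == pytest.approx(50.0, abs=3.0)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 10))
        a = fit_pca(X, 5)
        b = fit_pca(X, 5)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_orthonormal_loadings_and_monotone_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 8)) * np.arange(1, 9)
        model = fit_pca(X, 6)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_pct) <= 1e-9)

    def test_n_components_bounds(self):
        X = np.random.default_rng(0).normal(0, 1, (5, 10))
        with pytest.raises(ValueError):
            fit_pca(X, 5)  # > n_samples − 1
        with pytest.raises(ValueError):
            fit_pca(X, 0)


class TestPCLDA:
    def test_separable_classes_train_perfectly(self):
        M = two_class_blobs(sep=8.0)
        model = fit_pclda(M, n_pcs="auto")
        preds = [predict_sample(model, x)[0] for x in M.X]
        assert preds == list(M.labels)

    def test_explicit_n_pcs_matches_auto_on_rank_one_signal(self):
        M = two_class_blobs(sep=10.0, n_dims=5, seed=3)
        auto = fit_pclda(M, n_pcs="auto")
        one = fit_pclda(M, n_pcs=1)
        preds_auto = [predict_sample(auto, x)[0] for x in M.X]
        preds_one = [predict_sample(one, x)[0] for x in M.X]
        assert preds_auto == preds_one

    def test_matches_sklearn_lda_decisions(self):
        """Dual route: our pooled-covariance LDA on PC scores must agree with
        sklearn's LDA fitted on the same scores."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        M = two_class_blobs(n_per_class=20, sep=2.5, seed=4)
        model = fit_pclda(M, n_pcs=5)
        scores = model.pca.transform(M.X)[:, :5]
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(scores, M.labels)
        ours = [predict_sample(model, x)[0] for x in M.X]
        theirs = list(sk.predict(scores))
        agreement = np.mean([o == t for o, t in zip(ours, theirs)])
        assert agreement == 1.0

    def test_small_class_rejected(self):
        M = make_matrix(np.random.default_rng(0).random((4, 6)),
                        ["normal", "normal", "normal", "cancer"])
        with pytest.raises(ValueError):
            fit_pclda(M)

    def test_non_binary_labels_rejected(self):
        M = make_matrix(np.random.default_rng(0).random((4, 6)),
                        ["normal", "normal", "hyperplasia", "cancer"])
        with pytest.raises(ValueError):
            fit_pclda(M)

    def test_prediction_invariant_to_constant_scaling(self):
        M = two_class_blobs(sep=3.0, seed=5)
        scaled = make_matrix(M.X * 7.5, M.labels)
        a = fit_pclda(M, n_pcs=3)
        b = fit_pclda(scaled, n_pcs=3)
        for x in M.X:
            assert predict_sample(a, x)[0] == predict_sample(b, 7.5 * x)[0]

    def test_predict_tie_goes_to_normal(self):
        pca = PCAModel(np.zeros(2), np.eye(2), np.array([60.0, 40.0]))
        model = PCLDAModel(pca, 2, np.array([1.0, 0.0]),
                           {"cancer": 1.0, "normal": -1.0}, threshold=0.0)
        label, score = predict_sample(model, np.array([0.0, 3.0]))
        assert label == "normal" and score == 0.0
        assert predict_sample(model, np.array([0.1, 0.0]))[0] == "cancer"

    def test_predict_wrong_length_rejected(self):
        M = two_class_blobs()
        model = fit_pclda(M, n_pcs=2)
        with pytest.raises(ValueError):
            predict_sample(model, np.ones(5))


class TestMetrics:
    def test_oracle_arithmetic(self):
        m = metrics_from_confusion(ConfusionTable(tp=50, fn=9, fp=6, tn=79))
        assert m.sensitivity == pytest.approx(84.7, abs=0.05)
        assert m.specificity == pytest.approx(92.9, abs=0.05)
        assert m.ppv == pytest.approx(89.3, abs=0.05)
        assert m.npv == pytest.approx(89.8, abs=0.05)
        assert m.accuracy == pytest.approx(89.6, abs=0.05)

    def test_perfect_and_degenerate_tables(self):
        perfect = metrics_from_confusion(ConfusionTable(10, 0, 0, 10))
        assert all(v == 100.0 for v in vars(perfect).values())
        degenerate = metrics_from_confusion(ConfusionTable(0, 5, 0, 5))
        assert degenerate.sensitivity == 0.0
        assert math.isnan(degenerate.ppv)  # undefined, not 0
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionTable(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 1)


class TestLOPO:
    def test_separable_cohort_is_perfect_and_total_is_preserved(self):
        M = two_class_blobs(n_per_class=8, sep=9.0, seed=6)
        confusion, metrics, preds = cross_validate_lopo(M, n_pcs=2)
        assert metrics.accuracy == 100.0
        assert confusion.total == M.n_samples == len(preds)

    def test_metrics_agree_with_recount_of_predictions(self):
        M = two_class_blobs(n_per_class=10, sep=1.0, seed=7)
        confusion, metrics, preds = cross_validate_lopo(M, n_pcs=3)
        tp = ((preds.truth == "cancer") & (preds.predicted == "cancer")).sum()
        tn = ((preds.truth == "normal") & (preds.predicted == "normal")).sum()
        assert confusion.tp == tp and confusion.tn == tn
        assert metrics.accuracy == pytest.approx(100.0 * (tp + tn) / len(preds))

    def test_patient_grouping_holds_out_all_samples_together(self):
        """Two samples per patient must always fall in the same fold."""
        rng = np.random.default_rng(8)
        X = np.abs(rng.normal(0, 1, (12, 6)))
        X[6:, 0] += 5
        labels = ["normal"] * 6 + ["cancer"] * 6
        patients = [f"P{i // 2}" for i in range(12)]  # P0..P5, two samples each
        M = FeatureMatrix([f"S{i}" for i in range(12)], patients, labels, X)
        confusion, _, preds = cross_validate_lopo(M, n_pcs=2)
        assert confusion.total == 12
        # both samples of each patient must carry the same fold ordering
        grouped = preds.groupby("patient_id").size()
        assert (grouped == 2).all()

    def test_fold_losing_a_class_errors(self):
        X = np.abs(np.random.default_rng(9).normal(0, 1, (6, 4)))
        labels = ["normal", "normal", "normal", "normal", "cancer", "cancer"]
        patients = ["P0", "P1", "P2", "P3", "P4", "P4"]  # all cancer on one patient
        M = FeatureMatrix([f"S{i}" for i in range(6)], patients, labels, X)
        with pytest.raises(ValueError, match="both classes"):
            cross_validate_lopo(M, n_pcs=2)


@pytest.fixture(scope="module")
def cohort():
    return two_class_blobs(n_per_class=12, sep=4.0, n_dims=8, seed=10)


class TestLearningCurve:

    def test_row_count_and_columns(self, cohort):
        lc = learning_curve(cohort, start_per_class=3, max_per_class=8,
                            n_iterations=5, seed=0)
        assert len(lc) == 6
        assert list(lc.k_per_class) == [3, 4, 5, 6, 7, 8]
        assert (lc.sd_accuracy >= 0).all()

    def test_determinism(self, cohort):
        a = learning_curve(cohort, 3, 1, 7, n_iterations=4, seed=11)
        b = learning_curve(cohort, 3, 1, 7, n_iterations=4, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = learning_curve(cohort, 3, 1, 7, n_iterations=4, seed=12)
        assert not a.equals(c)

    def test_max_per_class_bound_enforced(self, cohort):
        with pytest.raises(ValueError):
            learning_curve(cohort, 3, 1, 12, n_iterations=2, seed=0)
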