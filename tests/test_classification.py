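"""Lasso selection, kernel, metrics, and the LOOCV pipeline on planted cohorts."""

import numpy as np
import pytest
from scipy.stats import hypergeom

import morphnet as mn
from morphnet.classification import (
    EdgeFeatureMatrix,
    lambda_by_inner_cv,
    lasso_select,
    loocv_classify,
    roc_auc,
)


def orthonormal_design(rng, n, m):
    q, _ = np.linalg.qr(rng.standard_normal((n, m)))
    return q[:, :m]


class TestVectorize:
    def test_edge_count_68(self, small_network):
        F = mn.vectorize_edges([small_network], [1])
        assert F.n_edges == 2278

    def test_three_region_ordering(self):
        M = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.4], [0.3, 0.4, 1.0]])
        net = mn.SimilarityMatrix(M, ("a", "b", "c"))
        F = mn.vectorize_edges([net], [1])
        assert F.edge_index == ((0, 1), (0, 2), (1, 2))
        np.testing.assert_allclose(F.X[0], [0.2, 0.3, 0.4])

    def test_round_trip(self, small_network):
        F = mn.vectorize_edges([small_network], [1])
        M = mn.devectorize_edges(F.X[0], 68)
        off = small_network.values - np.diag(np.diag(small_network.values))
        np.testing.assert_allclose(M, off, atol=1e-12)

    def test_label_validation(self, small_network):
        with pytest.raises(ValueError, match=r"\+1 / -1"):
            mn.vectorize_edges([small_network], [2])


class TestLasso:
    def test_empty_model_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        mu, sd = X.mean(0), X.std(0)
        lam_max = np.max(np.abs(((X - mu) / sd).T @ y))
        fit = lasso_select(X, y, lam_max * 1.0001)
        assert fit.selected == ()
        np.testing.assert_allclose(fit.w, 0)

    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        fit = lasso_select(X, y, 0.0, standardize=False)
        w_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.w, w_ls, atol=1e-8)

    def test_soft_threshold_closed_form(self):
        """On an orthonormal design the Lasso solution is exactly the
        soft-thresholded correlation vector."""
        rng = np.random.default_rng(2)
        X = orthonormal_design(rng, 40, 10)
        y = rng.standard_normal(40)
        beta = X.T @ y
        for lam in (0.05, 0.2, 0.5):
            fit = lasso_select(X, y, lam, standardize=False)
            expected = np.sign(beta) * np.maximum(np.abs(beta) - lam, 0)
            np.testing.assert_allclose(fit.w, expected, atol=1e-6)

    def test_support_monotone_along_path(self):
        rng = np.random.default_rng(3)
        X = orthonormal_design(rng, 50, 20)
        y = rng.standard_normal(50)
        supports = [
            set(lasso_select(X, y, lam, standardize=False).selected)
            for lam in (0.01, 0.05, 0.15, 0.4, 1.0)
        ]
        for small_lam, big_lam in zip(supports, supports[1:]):
            assert big_lam <= small_lam

    def test_objective_vs_subgradient_reference(self):
        """Coordinate descent reaches the same objective value as a projected
        subgradient reference on random over-determined problems."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        lam = 1.0

        def objective(w):
            return 0.5 * np.sum((X @ w - y) ** 2) + lam * np.sum(np.abs(w))

        fit = lasso_select(X, y, lam, standardize=False)
        # ISTA reference with step 1/L
        L = np.linalg.norm(X, 2) ** 2
        w = np.zeros(50)
        for _ in range(20000):
            g = X.T @ (X @ w - y)
            w = w - g / L
            w = np.sign(w) * np.maximum(np.abs(w) - lam / L, 0)
        assert objective(fit.w) <= objective(w) + 1e-6

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lasso_select(np.array([[np.inf, 1.0]]), np.array([1.0]), 0.1)


class TestKernelAndMetrics:
    def test_rbf_identity_and_closed_form(self):
        x = np.array([1.0, 2.0])
        assert mn.rbf_kernel(x, x, 1.5) == 1.0
        sigma = 0.7
        y = x + np.array([sigma * np.sqrt(2), 0.0])
        assert mn.rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1))

    def test_rbf_matches_formula_random(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.standard_normal(8), rng.standard_normal(8)
        sigma = 1.3
        expected = np.exp(-np.sum((x1 - x2) ** 2) / (2 * sigma**2))
        assert mn.rbf_kernel(x1, x2, sigma) == pytest.approx(expected, abs=1e-12)

    def test_rbf_invalid_sigma(self):
        with pytest.raises(ValueError):
            mn.rbf_kernel(np.zeros(2), np.ones(2), 0.0)

    def test_confusion_hand_counted(self):
        y_true = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, -1, -1, 1, 1])
        acc, sens, spec = mn.confusion_metrics(y_true, y_pred)
        assert (acc, sens, spec) == (0.625, 0.75, 0.5)

    def test_confusion_perfect_and_degenerate(self):
        y = np.array([1, -1, 1])
        assert mn.confusion_metrics(y, y) == (1.0, 1.0, 1.0)
        acc, sens, spec = mn.confusion_metrics(y, np.array([1, 1, 1]))
        assert sens == 1.0 and spec == 0.0
        acc, sens, spec = mn.confusion_metrics(np.array([1, 1]), np.array([1, -1]))
        assert np.isnan(spec)

    def test_auc_pair_counting(self):
        y = np.array([1, 1, -1, -1])
        s = np.array([0.9, 0.4, 0.5, 0.1])
        roc, auc = roc_auc(y, s)
        assert auc == pytest.approx(3 / 4)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_auc_perfect_and_reversed(self):
        y = np.array([1, 1, -1, -1])
        s = np.array([2.0, 1.5, 0.5, 0.1])
        _, auc = roc_auc(y, s)
        assert auc == 1.0
        _, auc_rev = roc_auc(y, -s)
        assert auc_rev == pytest.approx(1 - auc)

    def test_constant_scores(self):
        _, auc = roc_auc(np.array([1, -1]), np.array([0.3, 0.3]))
        assert auc == 0.5

    def test_sweep_auc_equals_trapezoid_on_random_scores(self):
        """The pair-counting AUC must equal the area under the swept ROC."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.standard_normal(n), 1)  # coarse: force ties
            roc, auc = roc_auc(y, s)
            pts = np.array(roc)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert auc == pytest.approx(area, abs=1e-10)
            assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)


def planted_feature_matrix(rng, n_per_group=12, m=60, n_informative=8, effect=3.0):
    """Direct synthetic edge-feature matrix with a planted mean shift."""
    y = np.array([-1] * n_per_group + [1] * n_per_group)
    X = rng.standard_normal((2 * n_per_group, m))
    X[y == 1, :n_informative] += effect
    edge_index = tuple(
        (i, j) for i in range(20) for j in range(i + 1, 20)
    )[:m]
    return EdgeFeatureMatrix(X, y, edge_index, tuple(f"r{i}" for i in range(20)))


class TestLOOCV:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(7)
        F = planted_feature_matrix(rng, effect=3.0)
        rep = loocv_classify(
            F, lambda_mode="auto", C_grid=(1.0, 8.0), sigma_grid=(1.0, 4.0), seed=0
        )
        assert rep.accuracy >= 0.95
        assert rep.auc >= 0.95

    def test_permuted_labels_chance_level(self):
        """Under label permutation the grid-searched pipeline scores within
        the 95% binomial band around 0.5 (the grid must span kernel widths
        matched to the selected-feature dimension, else the SVM degenerates
        to a constant majority vote)."""
        rng = np.random.default_rng(8)
        F = planted_feature_matrix(rng, n_per_group=20, effect=3.0)
        yperm = rng.permutation(F.y)
        Fp = EdgeFeatureMatrix(F.X, yperm, F.edge_index, F.labels)
        rep = loocv_classify(
            Fp, lambda_mode=2.0, C_grid=(1.0, 8.0), sigma_grid=(2.0, 8.0), seed=0
        )
        n = Fp.n_subjects
        band = 1.96 * np.sqrt(0.25 / n)
        assert abs(rep.accuracy - 0.5) <= band + 1e-9

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for effect in (0.0, 1.0, 3.0):
            rng = np.random.default_rng(9)
            F = planted_feature_matrix(rng, effect=effect)
            rep = loocv_classify(
                F, lambda_mode="auto", C_grid=(1.0,), sigma_grid=(2.0,), seed=0
            )
            accs.append(rep.accuracy)
        assert accs[0] <= accs[1] + 0.1
        assert accs[1] <= accs[2]
        assert accs[2] >= 0.9

    def test_no_leakage_from_held_out_row(self):
        """Corrupting the held-out subject's features never changes that
        fold's training-side edge selection."""
        rng = np.random.default_rng(10)
        F = planted_feature_matrix(rng, n_per_group=6, m=30)
        rep = loocv_classify(F, lambda_mode=3.0, C_grid=(1.0,), sigma_grid=(1.0,), seed=0)
        X2 = F.X.copy()
        X2[3] = 1e3 * rng.standard_normal(F.n_edges)
        F2 = EdgeFeatureMatrix(X2, F.y, F.edge_index, F.labels)
        rep2 = loocv_classify(F2, lambda_mode=3.0, C_grid=(1.0,), sigma_grid=(1.0,), seed=0)
        assert rep.folds[3].selected == rep2.folds[3].selected

    def test_determinism(self):
        rng = np.random.default_rng(11)
        F = planted_feature_matrix(rng, n_per_group=6, m=30)
        r1 = loocv_classify(F, lambda_mode=2.0, C_grid=(1.0, 4.0), sigma_grid=(1.0,), seed=5)
        r2 = loocv_classify(F, lambda_mode=2.0, C_grid=(1.0, 4.0), sigma_grid=(1.0,), seed=5)
        assert [f.prediction for f in r1.folds] == [f.prediction for f in r2.folds]
        assert r1.accuracy == r2.accuracy

    def test_empty_selection_falls_back_to_all_edges(self):
        rng = np.random.default_rng(12)
        F = planted_feature_matrix(rng, n_per_group=4, m=20, effect=0.0)
        rep = loocv_classify(
            F, lambda_mode=1e6, C_grid=(1.0,), sigma_grid=(1.0,), seed=0
        )
        assert all(f.fallback_all_edges for f in rep.folds)
        assert rep.extras["n_fallback_folds"] == F.n_subjects

    def test_nested_protocol_runs(self):
        rng = np.random.default_rng(13)
        F = planted_feature_matrix(rng, n_per_group=5, m=20, effect=3.0)
        rep = loocv_classify(
            F,
            lambda_mode=2.0,
            C_grid=(1.0, 8.0),
            sigma_grid=(1.0,),
            seed=0,
            protocol="nested",
            inner_folds=3,
        )
        assert rep.protocol == "nested"
        assert rep.accuracy >= 0.8

    def test_too_few_subjects(self):
        rng = np.random.default_rng(14)
        F = planted_feature_matrix(rng, n_per_group=1, m=10)
        with pytest.raises(ValueError):
            loocv_classify(F, lambda_mode=1.0)


class TestDiscriminativeEdges:
    def _report_with_selections(self, selections, F):
        from morphnet.classification import ClassificationReport, FoldRecord

        folds = [
            FoldRecord(t, tuple(sel), 1, 0.5) for t, sel in enumerate(selections)
        ]
        return ClassificationReport(
            accuracy=1.0, sensitivity=1.0, specificity=1.0, auc=1.0, roc=[],
            folds=folds, C=1.0, sigma_rbf=1.0, protocol="literal", lambda_mode="1",
        )

    def test_strict_intersection(self):
        rng = np.random.default_rng(15)
        F = planted_feature_matrix(rng, n_per_group=3, m=10)
        rep = self._report_with_selections([(0, 1, 2), (0, 2, 5), (2, 0)], F)
        out = mn.discriminative_edges(rep, F)
        assert out["columns"] == [0, 2]  # 1 and 5 miss at least one fold

    def test_hemisphere_tagging(self, parcellation, small_network):
        F = mn.vectorize_edges([small_network] * 4, [1, 1, -1, -1])
        rep = self._report_with_selections([(0, 40, 2277)] * 4, F)
        out = mn.discriminative_edges(rep, F, parcellation)
        tags = {e["edge"]: e["hemisphere_tag"] for e in out["edges"]}
        assert tags[0] == "intra_L"  # edge (0,1): both left hemisphere
        assert tags[2277] == "intra_R"  # last edge (66,67): both right
        assert sum(out["hemisphere_counts"].values()) == 3


class TestScoreCorrelation:
    def test_exact_copy_r_one(self):
        rng = np.random.default_rng(16)
        F = planted_feature_matrix(rng, n_per_group=8, m=20)
        out = mn.correlate_edges_with_scores(F, [4], F.X[:, 4])
        assert out[0]["r"] == pytest.approx(1.0)
        assert out[0]["significant"]

    def test_null_calibration(self):
        """Independent scores flag ~5% of edges at p < 0.05."""
        rng = np.random.default_rng(17)
        n, m = 60, 1500
        F = EdgeFeatureMatrix(
            rng.standard_normal((n, m)), np.array([1, -1] * 30),
            tuple((0, j) for j in range(1, m + 1)), (),
        )
        scores = rng.standard_normal(n)
        out = mn.correlate_edges_with_scores(F, range(m), scores)
        frac = np.mean([o["significant"] for o in out])
        assert 0.03 < frac < 0.07

    def test_constant_score_skipped(self):
        rng = np.random.default_rng(18)
        F = planted_feature_matrix(rng, n_per_group=4, m=10)
        out = mn.correlate_edges_with_scores(F, [0, 1], np.full(F.n_subjects, 2.0))
        assert all(o["skipped"] for o in out)
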