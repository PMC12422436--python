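"""Selection methods against hand and library oracles; leakage guards."""

import numpy as np
import pytest

from spermvision.selection import (ALL_METHODS, BASE_METHODS, INTERSECTION_METHODS,
                                   apply_selection, chi2_scores, default_k,
                                   fit_selector, intersect_selections,
                                   pca_feature_importance, select_features)


class TestChiSquare:
    def test_two_class_toy_matches_hand_computation(self):
        """Rows (1,0),(1,0),(0,1),(0,1), labels (0,0,1,1): both features
        carry identical association, scores tie, tie-break selects index 0."""
        x = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        scores = chi2_scores(x, y)
        # hand contingency: feature totals 2, priors 0.5 -> E = 1 per cell;
        # O = (2,0) and (0,2) -> sum (O-E)^2/E = 1+1 = 2 for both features
        assert np.allclose(scores, [2.0, 2.0])
        sel = select_features(x, y, "chi2", k=1)
        assert sel.indices.tolist() == [0]

    def test_matches_sklearn_chi2_on_nonnegative_data(self):
        from sklearn.feature_selection import chi2 as sk_chi2

        rng = np.random.default_rng(0)
        x = rng.random((20, 6))
        y = rng.integers(0, 3, 20)
        # same scaling applied on both routes: our scorer min-max scales first
        lo, hi = x.min(axis=0), x.max(axis=0)
        xs = (x - lo) / (hi - lo)
        assert np.allclose(chi2_scores(x, y), sk_chi2(xs, y)[0], atol=1e-9)

    def test_all_zero_feature_scores_zero(self):
        x = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0], [0.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        scores = chi2_scores(x, y)
        assert scores[0] == 0.0


class TestPCA:
    def test_axis_aligned_loadings(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 3)) * np.sqrt([4.0, 1.0, 0.1])
        sel = select_features(x, None, "pca", k=2)
        v = sel.components
        assert abs(v[0, 0]) > 0.99   # first component along column 0
        assert abs(v[1, 1]) > 0.99   # second along column 1

    def test_projection_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 5))
        sel = select_features(x, None, "pca", k=3)
        cov = np.cov(x, rowvar=False)
        w, v = np.linalg.eigh(cov)
        top = v[:, np.argsort(w)[::-1][:3]]
        proj = apply_selection(x, sel)
        ref = (x - x.mean(axis=0)) @ top
        # eigenvectors are sign/rotation ambiguous only per column here
        for j in range(3):
            assert np.allclose(np.abs(proj[:, j]), np.abs(ref[:, j]), atol=1e-8)

    def test_components_orthonormal(self):
        x = np.random.default_rng(3).normal(size=(40, 8))
        sel = select_features(x, None, "pca", k=4)
        gram = sel.components.T @ sel.components
        assert np.allclose(gram, np.eye(4), atol=1e-6)

    def test_reconstruction_error_non_increasing_in_k(self):
        x = np.random.default_rng(4).normal(size=(50, 6))
        errs = []
        for k in range(1, 7):
            sel = select_features(x, None, "pca", k=k)
            proj = apply_selection(x, sel)
            recon = proj @ sel.components.T + sel.mean
            errs.append(np.sum((x - recon) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_heldout_rows_use_train_mean(self):
        rng = np.random.default_rng(5)
        train = rng.normal(size=(20, 4))
        test = rng.normal(size=(5, 4)) + 10.0     # far-off-center held-out rows
        sel = select_features(train, None, "pca", k=2)
        out = apply_selection(test, sel)
        assert np.allclose(out, (test - train.mean(axis=0)) @ sel.components)


class TestPcaFeatureImportance:
    def test_dominant_column_has_max_importance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(50, 4)) * np.array([10.0, 0.1, 0.1, 0.1])
        imp = pca_feature_importance(x, k=2)
        assert imp.argmax() == 0

    def test_duplicated_columns_equal_importance(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=50)
        x = np.column_stack([col, col, rng.normal(size=50) * 0.01])
        imp = pca_feature_importance(x, k=2)
        assert abs(imp[0] - imp[1]) < 1e-9

    def test_matches_explicit_eigenvector_recomputation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 4))
        k = 2
        imp = pca_feature_importance(x, k)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (len(x) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:k]
        evr = w[order] / w.sum()
        ref = np.abs(v[:, order]) @ evr
        assert np.allclose(imp, ref, atol=1e-9)


class TestVarianceAndRF:
    def test_variance_drops_constant_column(self):
        x = np.column_stack([np.ones(10), np.random.default_rng(9).normal(size=10)])
        sel = select_features(x, None, "variance", k=1)
        assert sel.indices.tolist() == [1]

    def test_rf_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(30, 6))
        y = (x[:, 2] > 0).astype(int)
        a = select_features(x, y, "rf", k=3, seed=5)
        b = select_features(x, y, "rf", k=3, seed=5)
        assert np.array_equal(a.indices, b.indices)

    def test_rf_finds_informative_feature(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(60, 5))
        y = (x[:, 3] > 0).astype(int)
        sel = select_features(x, y, "rf", k=1, seed=0)
        assert sel.indices.tolist() == [3]


class TestIntersections:
    def test_identical_rankings_self_intersect_to_top_k(self):
        rng = np.random.default_rng(12)
        # variance and chi2 agree when one feature dominates both criteria
        x = rng.random((20, 6))
        x[:, 0] *= 5
        y = rng.integers(0, 2, 20)
        sel = intersect_selections("variance", "chi2", x, y, k=3, seed=0)
        assert 0 in sel.indices
        assert len(sel.indices) >= 2

    def test_disjoint_topk_falls_back_to_mean_rank_pair(self):
        # engineered scores: variance ranks (0,1) top, chi2 ranks (2,3) top
        x = np.zeros((8, 4))
        rng = np.random.default_rng(13)
        x[:, 0] = rng.normal(0, 10, 8)          # huge variance, label-free
        x[:, 1] = rng.normal(0, 5, 8)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x[:, 2] = y * 0.6                        # label-aligned, low variance
        x[:, 3] = y * 0.5
        sel = intersect_selections("variance", "chi2", x, y, k=2, seed=0)
        assert len(sel.indices) == 2
        assert set(sel.indices) <= {0, 1, 2, 3}

    def test_exactly_six_hybrid_pairs(self):
        assert len(INTERSECTION_METHODS) == 6
        pairs = {tuple(sorted(m.split("∩"))) for m in INTERSECTION_METHODS}
        assert len(pairs) == 6
        from itertools import combinations

        assert pairs == {tuple(sorted(p)) for p in combinations(BASE_METHODS, 2)}

    def test_same_method_rejected(self):
        with pytest.raises(ValueError):
            intersect_selections("pca", "pca", np.zeros((4, 4)), None, k=2)


class TestApplyAndContracts:
    def test_identity_index_selection(self):
        x = np.random.default_rng(14).normal(size=(6, 5))
        y = np.array([0, 0, 0, 1, 1, 1])
        sel = select_features(x, y, "variance", k=5)
        assert np.array_equal(apply_selection(x, sel), x)

    def test_double_application_of_index_payload_raises(self):
        x = np.random.default_rng(15).normal(size=(10, 8))
        sel = select_features(x, None, "variance", k=2)
        once = apply_selection(x, sel)
        if sel.indices.max() >= once.shape[1]:
            with pytest.raises(ValueError, match="columns"):
                apply_selection(once, sel)

    def test_dimension_mismatch_named(self):
        x = np.random.default_rng(16).normal(size=(10, 8))
        sel = select_features(x, None, "pca", k=2)
        with pytest.raises(ValueError, match="8"):
            apply_selection(np.zeros((3, 5)), sel)

    def test_k_larger_than_d_clipped_with_warning(self):
        x = np.random.default_rng(17).normal(size=(10, 4))
        with pytest.warns(UserWarning, match="clip"):
            sel = select_features(x, None, "variance", k=9)
        assert sel.output_dim == 4

    def test_nonfinite_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            select_features(x, None, "variance", k=1)


def test_eight_to_one_reduction_for_all_ten_methods():
    rng = np.random.default_rng(18)
    x = rng.random((40, 32))
    y = rng.integers(0, 3, 40)
    k = default_k(32)
    assert k == 4
    for method in ALL_METHODS:
        sel = fit_selector(method, x, y, k=k, seed=0)
        out = apply_selection(x, sel)
        if method in BASE_METHODS:
            assert out.shape[1] == k, method
        else:   # intersections may be smaller but never below 2
            assert 2 <= out.shape[1] <= k, method


def test_selection_changes_when_training_rows_change():
    """Leakage guard: the fitted selector is a function of its training
    rows, so perturbing them changes the outcome."""
    rng = np.random.default_rng(19)
    x = rng.normal(size=(30, 10))
    y = rng.integers(0, 2, 30)
    sel_a = select_features(x, y, "variance", k=2)
    x2 = x.copy()
    x2[:10, 7] += 100.0     # inflate one feature's variance in the "train" rows
    sel_b = select_features(x2, y, "variance", k=2)
    assert not np.array_equal(sel_a.indices, sel_b.indices)
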