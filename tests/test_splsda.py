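"""Sparse PLS-DA: soft thresholding, fitting, prediction, block fusion."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from cardioprofiler.splsda import (
    SparsePLSDA,
    block_combine,
    one_hot,
    soft_threshold_select,
)


class TestOneHot:
    def test_example(self):
        Y, classes = one_hot(["a", "b", "a"])
        np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [1, 0]])
        assert classes == ["a", "b"]

    def test_row_sums_one_and_column_sums_counts(self):
        labels = ["x", "y", "y", "z", "x", "x"]
        Y, classes = one_hot(labels)
        np.testing.assert_array_equal(Y.sum(axis=1), np.ones(6))
        assert dict(zip(classes, Y.sum(axis=0))) == {"x": 3, "y": 2, "z": 1}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            one_hot(["a", "a"])


class TestSoftThreshold:
    def test_hand_computed_example(self):
        u = soft_threshold_select(np.array([0.9, -0.4, 0.1]), keep=2)
        expected = np.array([0.8, -0.3, 0.0])
        np.testing.assert_allclose(u, expected / np.linalg.norm(expected), atol=1e-12)

    def test_keep_all_preserves_support_and_normalizes(self):
        w = np.array([3.0, -1.0, 2.0])
        u = soft_threshold_select(w, keep=3)
        np.testing.assert_allclose(u, w / np.linalg.norm(w), atol=1e-12)

    def test_keep_one_is_unit_vector_at_argmax(self):
        u = soft_threshold_select(np.array([0.2, -0.9, 0.5]), keep=1)
        np.testing.assert_allclose(u, [0.0, -1.0, 0.0], atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold_select(np.zeros(4), keep=2)

    def test_unit_norm_and_support_bound(self):
        rng = np.random.default_rng(5)
        for keep in (1, 3, 7, 10):
            w = rng.normal(size=10)
            u = soft_threshold_select(w, keep)
            assert np.linalg.norm(u) == pytest.approx(1.0)
            assert np.count_nonzero(u) <= keep

    def test_sparsity_monotone_in_keep(self):
        rng = np.random.default_rng(9)
        w = rng.normal(size=30)
        supports = [
            set(np.flatnonzero(soft_threshold_select(w, keep)))
            for keep in (30, 20, 10, 5, 1)
        ]
        for bigger, smaller in zip(supports, supports[1:]):
            assert smaller <= bigger

    def test_ties_at_lambda_first_index_priority(self):
        u = soft_threshold_select(np.array([1.0, 0.5, 0.5, 0.5]), keep=2)
        assert np.count_nonzero(u) <= 2


def _class_data(n_per=10, p=8, seed=0, sep=3.0):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for g, cls in enumerate(["a", "b", "c"]):
        mu = np.zeros(p)
        mu[g] = sep
        X.append(rng.normal(size=(n_per, p)) + mu)
        labels += [cls] * n_per
    return np.vstack(X), labels


class TestFit:
    def test_single_separating_feature_found(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6)) * 0.1
        labels = ["a"] * 15 + ["b"] * 15
        X[:15, 3] += 5.0
        res = SparsePLSDA(X, labels, n_components=1, keep_x=1).fit()
        assert np.flatnonzero(res.x_weights[:, 0]).tolist() == [3]
        pred = res.predict(pd.DataFrame(X), true_labels=labels)
        assert pred.accuracy_pct == pytest.approx(100.0)

    def test_score_orthogonality(self):
        X, labels = _class_data(n_per=10, p=10, seed=4)
        res = SparsePLSDA(X, labels, n_components=3, keep_x=10).fit()
        T = res.scores
        for h in range(3):
            for j in range(h + 1, 3):
                assert abs(T[:, h] @ T[:, j]) < 1e-8

    def test_keepx_full_matches_dense_reference(self):
        """With keepX = p the fit reproduces dense PLS-DA scores to 1e-8."""
        X, labels = _class_data(n_per=8, p=7, seed=6)
        res = SparsePLSDA(X, labels, n_components=3, keep_x=7).fit()
        T_ref = dense_plsda_reference(X, labels, 3)
        for h in range(3):
            a, b = res.scores[:, h], T_ref[:, h]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_dense_case_matches_sklearn_pls_scores(self):
        X, labels = _class_data(n_per=8, p=7, seed=8)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Y, _ = one_hot(labels)
        res = SparsePLSDA(Xs, labels, n_components=2, keep_x=7, scale=False).fit()
        skl = PLSRegression(
            n_components=2, scale=False, tol=1e-14, max_iter=20000
        ).fit(Xs, Y - Y.mean(0))
        for h in range(2):
            a, b = res.scores[:, h], skl.x_scores_[:, h]
            sign = np.sign(a @ b)
            # sklearn's NIPALS stopping rule bounds the weight error near 1e-6
            # when consecutive singular values are close; exact agreement is
            # checked against the SVD reference above
            np.testing.assert_allclose(a, sign * b, atol=1e-4)

    def test_prediction_invariant_to_feature_rescaling(self):
        X, labels = _class_data(seed=10)
        scales = np.linspace(0.5, 20.0, X.shape[1])
        r1 = SparsePLSDA(X, labels, n_components=2, keep_x=4).fit()
        r2 = SparsePLSDA(X * scales + 7.0, labels, n_components=2, keep_x=4).fit()
        p1 = r1.predict(pd.DataFrame(X)).sample_labels
        p2 = r2.predict(pd.DataFrame(X * scales + 7.0)).sample_labels
        assert p1.tolist() == p2.tolist()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            SparsePLSDA(np.ones((2, 3)), ["a", "b"], n_components=2)

    def test_nonfinite_rejected(self):
        X = np.ones((6, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            SparsePLSDA(X, ["a", "a", "a", "b", "b", "b"])

    def test_summary_mentions_classes_and_components(self):
        X, labels = _class_data(seed=12)
        res = SparsePLSDA(X, labels, n_components=2, keep_x=4).fit()
        text = res.summary()
        assert "a, b, c" in text and "comp 1" in text and "comp 2" in text


def dense_plsda_reference(X, labels, n_components):
    """Independent dense PLS-DA (regression-mode NIPALS via exact SVD)."""
    Xh = (X - X.mean(0)) / X.std(0, ddof=1)
    Y, _ = one_hot(labels)
    Yh = Y - Y.mean(0)
    T = []
    for _ in range(n_components):
        u_, s_, vt_ = np.linalg.svd(Xh.T @ Yh, full_matrices=False)
        w = u_[:, 0]
        t = Xh @ w
        p = Xh.T @ t / (t @ t)
        q = Yh.T @ t / (t @ t)
        Xh = Xh - np.outer(t, p)
        Yh = Yh - np.outer(t, q)
        T.append(t)
    return np.column_stack(T)


class TestPredict:
    def test_training_data_on_separable_classes(self):
        X, labels = _class_data(sep=6.0, seed=14)
        res = SparsePLSDA(X, labels, n_components=2, keep_x=8).fit()
        pred = res.predict(pd.DataFrame(X), true_labels=labels)
        assert pred.accuracy_pct == pytest.approx(100.0)
        assert pred.confusion.to_numpy().sum() == len(labels)
        diag = np.diag(pred.confusion.reindex(index=res.classes, columns=res.classes).fillna(0))
        assert diag.sum() == len(labels)

    def test_majority_vote_accuracy_13_of_17(self):
        """13 of 17 compounds correct → 76.47%, printed as 76%."""
        rng = np.random.default_rng(16)
        compounds = [f"c{i:02d}" for i in range(17) for _ in (0, 1)]
        labels = ["a" if i < 13 else "b" for i in range(17) for _ in (0, 1)]
        X = rng.normal(size=(34, 5)) * 0.1
        X[np.array(labels) == "a", 0] += 4.0  # cleanly separable by training label
        res = SparsePLSDA(X, labels, n_components=1, keep_x=5).fit()
        # annotation disagrees with the (perfectly learned) labels on 4 compounds
        truth = {f"c{i:02d}": "a" for i in range(17)}
        pred = res.predict(pd.DataFrame(X), compounds=compounds, true_labels=truth)
        assert pred.compound_accuracy_pct == pytest.approx(100 * 13 / 17)
        assert round(pred.compound_accuracy_pct) == 76

    def test_empty_test_set_rejected(self):
        X, labels = _class_data()
        res = SparsePLSDA(X, labels, n_components=1, keep_x=2).fit()
        with pytest.raises(ValueError):
            res.predict(pd.DataFrame(np.empty((0, X.shape[1]))))

    def test_feature_mismatch_rejected(self):
        X, labels = _class_data()
        res = SparsePLSDA(pd.DataFrame(X), labels, n_components=1, keep_x=2).fit()
        bad = pd.DataFrame(np.ones((3, X.shape[1] - 1)))
        with pytest.raises(ValueError, match="feature mismatch"):
            res.predict(bad)


class TestBlockCombine:
    def test_identical_single_feature_blocks(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        Z = block_combine(a, a)
        np.testing.assert_allclose(Z.iloc[:, 0], Z.iloc[:, 1])

    def test_equal_total_variance_at_default_weights(self):
        rng = np.random.default_rng(18)
        morph = pd.DataFrame(rng.normal(size=(40, 30)))
        ephys = pd.DataFrame(rng.normal(size=(40, 5)))
        Z = block_combine(morph, ephys)
        morph_var = Z.iloc[:, :30].var(ddof=1).sum()
        ephys_var = Z.iloc[:, 30:].var(ddof=1).sum()
        assert morph_var == pytest.approx(ephys_var, rel=1e-9)

    def test_zero_weight_zeroes_a_block(self):
        rng = np.random.default_rng(20)
        morph = pd.DataFrame(rng.normal(size=(10, 4)))
        ephys = pd.DataFrame(rng.normal(size=(10, 3)))
        Z = block_combine(morph, ephys, weights=(1.0, 0.0))
        assert (Z.iloc[:, 4:] == 0).all().all()

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row mismatch"):
            block_combine(pd.DataFrame(np.ones((4, 2))), pd.DataFrame(np.ones((5, 2))))
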