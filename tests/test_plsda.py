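"""PLS-DA engine: NIPALS properties, oracle equivalence, CV, permutation
test and importance scores."""

import numpy as np
import pytest

import evspec.plsda as plsda_mod
from evspec.plsda import (
    coef_importance,
    encode_onehot,
    evaluate,
    fit_pls,
    loo_cv,
    permutation_test,
    predict_class,
    vip_scores,
)
from evspec.preprocess import preprocess_pipeline
from evspec.synthetic import default_config, generate_null_dataset


def _toy_two_class(rng, n=12, p=5):
    """Two classes perfectly determined by column 0."""
    X = rng.normal(size=(n, p))
    labels = np.array(["pos" if i % 2 else "neg" for i in range(n)], dtype=object)
    X[:, 0] = [3.0 if l == "pos" else -3.0 for l in labels]
    return X, labels


class TestFitPLS:
    def test_single_informative_column_separates(self, rng):
        X, labels = _toy_two_class(rng)
        Y, order = encode_onehot(labels)
        model = fit_pls(X, Y, 1, order)
        assert list(predict_class(model, X)) == list(labels)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(20, 15))
        Y, order = encode_onehot(np.array(list("ABC") * 6 + ["A", "B"], dtype=object))
        model = fit_pls(X, Y, 5, order)
        T = model.x_scores
        for i in range(5):
            for j in range(i + 1, 5):
                dot = abs(T[:, i] @ T[:, j])
                assert dot < 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])

    def test_training_prediction_matches_deflation_fit(self, rng):
        """ŷ = ȳ + (x−x̄)·B reproduces the deflation algorithm's fit T·Cᵀ."""
        X = rng.normal(size=(15, 8))
        Y, order = encode_onehot(np.array(list("AB") * 7 + ["C"], dtype=object))
        model = fit_pls(X, Y, 4, order)
        via_coef = model.predict(X)
        via_scores = model.y_mean + model.x_scores @ model.y_loadings.T
        np.testing.assert_allclose(via_coef, via_scores, atol=1e-10)

    def test_matches_sklearn_nipals_oracle(self, rng):
        """Predictions agree with scikit-learn's PLSRegression to 1e-6."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 5))
        labels = np.array(["a", "b"] * 6, dtype=object)
        Y, order = encode_onehot(labels)
        model = fit_pls(X, Y, 3, order)
        ref = sklearn_pls.PLSRegression(n_components=3, scale=False).fit(X, Y)
        Xq = rng.normal(size=(6, 5))
        np.testing.assert_allclose(model.predict(Xq), ref.predict(Xq), atol=1e-6)

    def test_feature_permutation_invariance(self, rng):
        X, labels = _toy_two_class(rng)
        Y, order = encode_onehot(labels)
        perm = rng.permutation(X.shape[1])
        m1 = fit_pls(X, Y, 2, order)
        m2 = fit_pls(X[:, perm], Y, 2, order)
        Xq = rng.normal(size=(5, X.shape[1]))
        assert list(predict_class(m1, Xq)) == list(predict_class(m2, Xq[:, perm]))

    def test_mean_query_predicts_mean_response(self, rng):
        X = rng.normal(size=(9, 4))
        labels = np.array(list("ABC") * 3, dtype=object)
        Y, order = encode_onehot(labels)
        model = fit_pls(X, Y, 2, order)
        np.testing.assert_allclose(model.predict(model.x_mean[None, :])[0], model.y_mean,
                                   atol=1e-12)
        # balanced classes: argmax of y_mean ties -> first class in order
        assert predict_class(model, model.x_mean[None, :])[0] == order[0]

    def test_degenerate_inputs_rejected(self, rng):
        X = np.zeros((6, 3))
        Y, order = encode_onehot(np.array(list("AB") * 3, dtype=object))
        with pytest.raises(ValueError):
            fit_pls(X, Y, 1, order)
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(6, 3)), Y, 6, order)


class TestLooCV:
    def test_separable_data_perfect_accuracy(self, rng):
        X, labels = _toy_two_class(rng)
        optimal_a, acc, q2, _, _ = loo_cv(X, labels, 3)
        assert acc == 1.0
        assert q2 > 0.5

    def test_null_data_q2_not_positive(self):
        cfg = default_config(seed=11, n_per_group=10)
        cfg.axis_step = 8.0
        spectra, _ = generate_null_dataset(cfg)
        pre = preprocess_pipeline(spectra)
        _, acc, q2, _, q2_per_a = loo_cv(pre.intensities, pre.labels, 4)
        assert q2 < 0.2
        assert np.min(q2_per_a) < 0.0 or acc < 0.6

    def test_uninformative_feature_barely_matters(self, rng):
        X, labels = _toy_two_class(rng, n=16, p=6)
        _, acc_full, _, _, _ = loo_cv(X, labels, 2)
        _, acc_drop, _, _, _ = loo_cv(X[:, :-1], labels, 2)
        assert abs(acc_full - acc_drop) <= 0.15

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        labels = np.array(["a", "a", "b", "b", "c"], dtype=object)
        with pytest.raises(ValueError, match="fewer than 2"):
            loo_cv(X, labels, 2)

    def test_jit_and_numpy_paths_agree(self, rng):
        X = rng.normal(size=(18, 12))
        labels = np.array(list("ABC") * 6, dtype=object)
        out_jit = loo_cv(X, labels, 4)
        old = plsda_mod._HAVE_NUMBA
        plsda_mod._HAVE_NUMBA = False
        try:
            out_np = loo_cv(X, labels, 4)
        finally:
            plsda_mod._HAVE_NUMBA = old
        np.testing.assert_allclose(out_jit[3], out_np[3], atol=1e-12)
        np.testing.assert_allclose(out_jit[4], out_np[4], atol=1e-9)


class TestPermutationTest:
    def test_separable_data_minimal_p(self, rng):
        """Separable 3-class data: no permutation ties the observed maximum,
        so the add-one p-value is exactly 1/(n_perm + 1)."""
        n = 15
        labels = np.array(list("ABC") * (n // 3), dtype=object)
        X = rng.normal(size=(n, 6))
        centers = {"A": (4.0, 0.0), "B": (0.0, 4.0), "C": (-4.0, -4.0)}
        for i, l in enumerate(labels):
            X[i, 0] += centers[l][0]
            X[i, 1] += centers[l][1]
        p, obs, perm_acc = permutation_test(X, labels, n_perm=99, seed=1, a_max=2)
        assert obs == 1.0
        assert p == pytest.approx(1 / 100)

    def test_relabeling_invariance(self, rng):
        X = rng.normal(size=(15, 6))
        labels = np.array(list("ABC") * 5, dtype=object)
        p1, _, _ = permutation_test(X, labels, n_perm=99, seed=5)
        remap = {"A": "x", "B": "y", "C": "z"}
        relabeled = np.array([remap[l] for l in labels], dtype=object)
        p2, _, _ = permutation_test(X, relabeled, n_perm=99, seed=5)
        assert p1 == p2

    def test_p_never_below_add_one_floor(self, rng):
        X, labels = _toy_two_class(rng)
        p, _, _ = permutation_test(X, labels, n_perm=99, seed=0, a_max=1)
        assert p >= 1 / 100


class TestImportance:
    def test_vip_normalisation_identity(self, profile_preprocessed):
        pre = profile_preprocessed
        Y, order = encode_onehot(pre.labels)
        model = fit_pls(pre.intensities, Y, 3, order)
        vip = vip_scores(model)
        p = pre.intensities.shape[1]
        assert np.sum(vip**2) == pytest.approx(p, rel=1e-8)

    def test_exchangeable_design_gives_flat_vip(self, rng):
        """Equally informative, identically distributed features → VIP ≈ 1."""
        n, p = 60, 6
        z = np.repeat([0.0, 1.0], n // 2)
        X = z[:, None] + 0.8 * rng.normal(size=(n, p))
        labels = np.array(["a" if v == 0 else "b" for v in z], dtype=object)
        Y, order = encode_onehot(labels)
        vip = vip_scores(fit_pls(X, Y, 1, order))
        np.testing.assert_allclose(vip, 1.0, atol=0.25)

    def test_coef_importance_class_symmetry_and_zeros(self, rng):
        X, labels = _toy_two_class(rng)
        X[:, 3] = 0.0  # dead feature: no variance, no coefficient
        Y, order = encode_onehot(labels)
        imp = coef_importance(fit_pls(X, Y, 2, order))
        flipped = np.array(["neg" if l == "pos" else "pos" for l in labels], dtype=object)
        Y2, order2 = encode_onehot(flipped)
        imp2 = coef_importance(fit_pls(X, Y2, 2, order2))
        np.testing.assert_allclose(imp, imp2, atol=1e-12)
        assert imp[3] == pytest.approx(0.0, abs=1e-20)

    def test_vip_and_coef_importance_rank_similarly(self, profile_preprocessed):
        from scipy import stats

        pre = profile_preprocessed
        Y, order = encode_onehot(pre.labels)
        model = fit_pls(pre.intensities, Y, 3, order)
        rho = stats.spearmanr(vip_scores(model), coef_importance(model)).statistic
        assert rho > 0.5


class TestEvaluate:
    def test_r2_at_least_q2(self, rng):
        X = rng.normal(size=(20, 8))
        X[:, 0] += np.repeat([0.0, 2.0], 10)
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        perf = evaluate(X, labels, n_perm=99, seed=2, a_max=4)
        assert perf.r2 >= perf.q2 - 1e-10
        assert 0 <= perf.accuracy <= 1
        assert perf.permutation_p > 0

    def test_null_data_accuracy_near_chance(self):
        cfg = default_config(seed=29, n_per_group=12)
        cfg.axis_step = 8.0
        spectra, _ = generate_null_dataset(cfg)
        pre = preprocess_pipeline(spectra)
        _, acc, _, _, _ = loo_cv(pre.intensities, pre.labels, 3)
        assert acc < 0.62  # chance is 1/3; LOO selection noise allows some excess
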