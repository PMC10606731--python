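"""Latent-variable models: oracle equivalences, invariants, metrics."""

import numpy as np
import pytest

from spicefuse.latent import (
    ConvergenceError,
    cross_validate,
    decode_classes,
    encode_classes,
    evaluate,
    explained_two_components,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    screen_by_vip,
    stratified_folds,
    vip_scores,
)


class TestEncodeClasses:
    def test_one_hot_rows(self):
        Y, codes = encode_classes(["A", "A", "B"])
        np.testing.assert_array_equal(Y, [[1, 0], [1, 0], [0, 1]])
        assert codes == ["A", "B"]

    def test_decode_inverts_encode(self):
        labels = list("ABCABCBBA")
        Y, codes = encode_classes(labels)
        assert decode_classes(Y, codes) == labels

    def test_thirteen_class_shape(self, study):
        Y, codes = encode_classes(study["nir"].labels)
        assert Y.shape == (195, 13)
        np.testing.assert_allclose(Y.sum(axis=1), 1.0)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            encode_classes(["A", "Z"], class_codes=["A", "B"])


class TestPCA:
    def test_rank_one_single_component(self):
        u = np.arange(1.0, 7.0)[:, None]
        v = np.array([[2.0, -1.0, 0.5]])
        model = fit_pca(u @ v, 1, scaling="none")
        assert model.r2x_per_component[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        """Component variances equal covariance eigenvalues on small matrices."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 8))
        model = fit_pca(X, 5)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        comp_ss = np.sum(model.x_scores**2, axis=0)
        np.testing.assert_allclose(comp_ss, eigvals[:5], rtol=1e-9)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 10))
        model = fit_pca(X, 4)
        ref = sklearn_pca(n_components=4).fit(X)
        np.testing.assert_allclose(
            np.abs(model.x_loadings), np.abs(ref.components_.T), rtol=1e-8
        )
        np.testing.assert_allclose(
            model.r2x_per_component, ref.explained_variance_ratio_, rtol=1e-8
        )

    def test_r2x_nonincreasing_cumulative_below_one(self, study):
        model = fit_pca(study["table"].contents, 6, scaling="autoscale")
        r2 = model.r2x_per_component
        assert np.all(np.diff(r2) <= 1e-12)
        assert r2.sum() <= 1.0 + 1e-12

    def test_scores_orthogonal(self, study):
        model = fit_pca(study["table"].contents, 5, scaling="autoscale")
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))


class TestPLSDA:
    def test_exact_univariate_fit(self):
        x = np.linspace(-2, 3, 12)[:, None]
        y = 1.5 * x
        model = fit_plsda(x, y, 1)
        assert model.r2y == pytest.approx(1.0)

    def test_full_rank_equals_least_squares(self):
        """At A = p on full-rank X, PLS coefficients equal the OLS solution."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=(30, 1))
        model = fit_plsda(X, y, 5, scaling="mean-center")
        Xc = X - X.mean(axis=0)
        yc = y - y.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-6)

    def test_matches_sklearn_pls(self):
        """Cross-check against an independent PLS2 implementation."""
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8))
        Y, _ = encode_classes(["A"] * 12 + ["B"] * 13)
        model = fit_plsda(X, Y, 3, scaling="mean-center")
        ref = PLSRegression(n_components=3, scale=False).fit(X, Y - Y.mean(axis=0))
        np.testing.assert_allclose(model.coefficients, ref.coef_.T, atol=1e-8)

    def test_separable_two_class_training_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(0, 0.3, (10, 4)), rng.normal(5, 0.3, (10, 4))]
        )
        labels = ["A"] * 10 + ["B"] * 10
        Y, codes = encode_classes(labels)
        model = fit_plsda(X, Y, 2, class_codes=codes)
        assert model.predict_labels(X) == labels

    def test_scores_orthogonal(self, toy_classes):
        X, labels = toy_classes
        Y, codes = encode_classes(labels)
        model = fit_plsda(X, Y, 6, class_codes=codes)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_training_fit_reproduced_by_coefficients(self, toy_classes):
        X, labels = toy_classes
        Y, codes = encode_classes(labels)
        model = fit_plsda(X, Y, 4, class_codes=codes)
        Yhat = model.predict(X)
        resid = Y - Yhat
        ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2)
        assert 1 - np.sum(resid**2) / ss_tot == pytest.approx(model.r2y, abs=1e-10)

    def test_degenerate_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ConvergenceError):
            fit_plsda(X, np.ones((6, 1)), 1)  # zero-variance response


class TestOPLSDA:
    def test_zero_orth_equals_plsda_predictions(self, toy_classes):
        X, labels = toy_classes
        Y, codes = encode_classes(labels)
        pls = fit_plsda(X, Y, 3, class_codes=codes)
        opls = fit_oplsda(X, Y, n_orth=0, n_predictive=3, class_codes=codes)
        np.testing.assert_allclose(opls.predict(X), pls.predict(X), atol=1e-10)

    def test_orthogonal_confound_absorbed(self):
        """Structured Y-uncorrelated variation lands in the orthogonal part."""
        rng = np.random.default_rng(6)
        n = 40
        labels = ["A"] * 20 + ["B"] * 20
        Y, codes = encode_classes(labels)
        signal = np.outer(Y[:, 0] - 0.5, rng.normal(1, 0.2, 6))
        X_clean = signal + rng.normal(0, 0.1, (n, 6))
        confound_score = np.tile([1.0, -1.0], 20)  # balanced across classes
        confound = np.outer(confound_score, rng.normal(2, 0.3, 6))
        X_conf = X_clean + confound
        clean = fit_oplsda(X_clean, Y, n_orth=0, n_predictive=1, class_codes=codes)
        filt = fit_oplsda(X_conf, Y, n_orth=1, n_predictive=1, class_codes=codes)
        assert filt.r2y == pytest.approx(clean.r2y, abs=0.05)
        # the orthogonal component carries substantial X-variation
        assert filt.r2x_orth_per_component[0] > 0.3

    def test_report_triple_on_study_data(self, study):
        table = study["table"]
        Y, codes = encode_classes(table.labels)
        model = fit_oplsda(
            table.contents, Y, n_orth=3, n_predictive=2, scaling="autoscale", class_codes=codes
        )
        r2x = np.sum(model.r2x_per_component) + np.sum(model.r2x_orth_per_component)
        assert 0 < r2x <= 1
        assert 0 <= model.r2y <= 1


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=20)
        X = np.column_stack([t, t]) + rng.normal(0, 1e-6, (20, 2))
        y = t[:, None]
        model = fit_plsda(X, y, 1)
        np.testing.assert_allclose(vip_scores(model), [1.0, 1.0], atol=1e-3)

    def test_mean_squared_vip_is_one(self, study):
        Y, codes = encode_classes(study["table"].labels)
        model = fit_plsda(
            study["table"].contents, Y, 5, scaling="autoscale", class_codes=codes
        )
        vip = vip_scores(model)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_matches_independent_formula(self, toy_classes):
        """Recompute VIP from scratch: scores, loadings, SSY per component."""
        X, labels = toy_classes
        Y, codes = encode_classes(labels)
        A = 3
        model = fit_plsda(X, Y, A, class_codes=codes)
        # independent re-derivation from the fitted T, C, W
        ssy = np.array(
            [
                (model.x_scores[:, a] @ model.x_scores[:, a])
                * (model.y_loadings[:, a] @ model.y_loadings[:, a])
                for a in range(A)
            ]
        )
        W = model.x_weights
        p = X.shape[1]
        expected = np.sqrt(
            p
            * np.sum(ssy * (W / np.linalg.norm(W, axis=0)) ** 2, axis=1)
            / ssy.sum()
        )
        np.testing.assert_allclose(vip_scores(model), expected, rtol=1e-10)

    def test_pca_model_rejected(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(10, 4)), 2)
        with pytest.raises(ValueError):
            vip_scores(model)

    def test_screening_boundary_inclusive(self, monkeypatch):
        import spicefuse.latent as latent

        monkeypatch.setattr(
            latent, "vip_scores", lambda model: np.array([1.2, 0.9, 1.0])
        )
        assert list(latent.screen_by_vip(object(), 1.0)) == [0, 2]
        assert list(latent.screen_by_vip(object(), 1.0, strict=True)) == [0]
        assert list(latent.screen_by_vip(object(), 99.0)) == []


class TestCrossValidation:
    def test_loo_matches_handrolled_loop(self):
        """Leave-one-out on a 6-sample toy equals an explicit refit loop."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(6, 3))
        labels = ["A", "B", "A", "B", "A", "B"]
        Y, _ = encode_classes(labels)
        q2, rmsecv = cross_validate(X, Y, 1, n_folds=3)
        folds = stratified_folds(labels, 3)
        press = ssy = 0.0
        for f in range(3):
            tr, te = folds != f, folds == f
            m = fit_plsda(X[tr], Y[tr], 1)
            press += np.sum((Y[te] - m.predict(X[te])) ** 2)
            ssy += np.sum((Y[te] - Y[tr].mean(axis=0)) ** 2)
        assert q2 == pytest.approx(1 - press / ssy, abs=1e-12)
        assert rmsecv == pytest.approx(np.sqrt(press / Y.size), abs=1e-12)

    def test_near_noiseless_q2_close_to_one(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(c, 0.01, (8, 5)) for c in (0.0, 4.0)])
        Y, _ = encode_classes(["A"] * 8 + ["B"] * 8)
        q2, _ = cross_validate(X, Y, 1, n_folds=4)
        assert q2 > 0.99

    def test_permuted_labels_give_nonpositive_q2(self):
        """With shuffled responses Q2 is <= 0 in expectation (seeded sim)."""
        rng = np.random.default_rng(14)
        q2s = []
        for _ in range(20):
            X = rng.normal(size=(24, 10))
            labels = list(rng.permutation(["A"] * 12 + ["B"] * 12))
            Y, _ = encode_classes(labels)
            q2, _ = cross_validate(X, Y, 2, n_folds=4)
            q2s.append(q2)
        assert np.mean(q2s) < 0.0

    def test_fold_losing_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        Y, _ = encode_classes(["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="entire class"):
            cross_validate(X, Y, 1, n_folds=4)


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(c, 0.001, (6, 4)) for c in (0.0, 5.0)])
        labels = ["A"] * 6 + ["B"] * 6
        Y, codes = encode_classes(labels)
        model = fit_plsda(X, Y, 2, class_codes=codes)
        m = evaluate(model, X, Y, X, Y)
        assert m.r2y > 0.999
        assert m.rmsee < 0.01
        assert m.accuracy_train == 100.0
        assert m.accuracy_test == 100.0

    def test_metrics_invariants_on_study(self, study):
        table = study["table"]
        Y, codes = encode_classes(table.labels)
        model = fit_plsda(table.contents, Y, 6, scaling="autoscale", class_codes=codes)
        q2, rmsecv = cross_validate(table.contents, Y, 6, scaling="autoscale")
        m = evaluate(model, table.contents, Y, table.contents, Y, q2=q2, rmsecv=rmsecv)
        m.validate()
        assert m.q2 <= m.r2y  # no-overfit direction on training data


class TestExplainedTwoComponents:
    @pytest.mark.parametrize(
        "fracs, expected",
        [
            ([0.165, 0.13], 29.5),
            ([0.0508, 0.0505], 10.13),
            ([0.5, 0.0], 50.0),
        ],
    )
    def test_reported_percentages(self, fracs, expected):
        assert explained_two_components(fracs) == pytest.approx(expected)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            explained_two_components([1.2, 0.1])
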