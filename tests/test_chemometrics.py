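"""Scaling, PCA and OPLS-DA against independent decomposition oracles."""

import numpy as np
import pytest

from stressnmr.chemometrics import (
    DegenerateFoldError,
    InsufficientDataError,
    cross_validated_q2,
    fit_oplsda,
    fit_pca,
    scale_columns,
)


def two_group_labels(n_control=6, n_case=7):
    return ["control"] * n_control + ["case"] * n_case


class TestScaling:
    def test_constant_column_centers_to_zero(self):
        X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            Xs, spec = scale_columns(X, "pareto")
        np.testing.assert_allclose(Xs[:, 0], 0.0)
        assert spec.divisors[0] == 1.0

    def test_pareto_divisor_is_sqrt_of_sd(self):
        X = np.column_stack([[-4.0, 0.0, 4.0], [0.0, 1.0, 2.0]])
        _, spec = scale_columns(X, "pareto")
        assert spec.column_sds[0] == pytest.approx(4.0)
        assert spec.divisors[0] == pytest.approx(2.0)

    def test_refit_on_scaled_data_matches_recomputation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 12)) * rng.uniform(0.1, 5.0, size=12)
        Xs, _ = scale_columns(X, "pareto")
        _, second = scale_columns(Xs, "pareto")
        np.testing.assert_allclose(
            second.divisors, np.sqrt(Xs.std(axis=0, ddof=1)), atol=1e-9
        )

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            scale_columns(np.ones((1, 4)), "pareto")


class TestPca:
    def test_rank_one_matrix_fully_explained_by_first_component(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.arange(1.0, 11.0)
        model = fit_pca(np.outer(u, v), k=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_svd_oracle_up_to_sign(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(6)
        for _ in range(3):
            X = rng.normal(size=(6, 50))
            ours = fit_pca(X, k=3)
            ref = sk.PCA(n_components=3).fit(X)
            for j in range(3):
                sign = np.sign(ours.loadings[:, j] @ ref.components_[j])
                np.testing.assert_allclose(
                    ours.loadings[:, j] * sign, ref.components_[j], atol=1e-8
                )
                np.testing.assert_allclose(
                    ours.scores[:, j] * sign,
                    ref.transform(X)[:, j],
                    atol=1e-8,
                )
            np.testing.assert_allclose(
                ours.explained_variance_fraction,
                ref.explained_variance_ratio_,
                atol=1e-10,
            )

    def test_loadings_orthonormal_and_variance_fractions_monotone(self):
        rng = np.random.default_rng(7)
        model = fit_pca(rng.normal(size=(10, 30)), k=4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        frac = model.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12) and np.all(frac >= 0)

    def test_duplicated_row_keeps_low_rank_principal_subspace(self):
        # exact rank-2 data: adding a duplicate row reweights the covariance
        # but cannot rotate the spanned subspace
        rng = np.random.default_rng(8)
        U = rng.normal(size=(6, 2)) @ np.diag([10.0, 3.0])
        V = np.linalg.qr(rng.normal(size=(20, 2)))[0]
        X = U @ V.T
        Xdup = np.vstack([X, X[0]])
        P1 = fit_pca(X, k=2).loadings
        P2 = fit_pca(Xdup, k=2).loadings
        np.testing.assert_allclose(P1 @ P1.T, P2 @ P2.T, atol=1e-6)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(4, 10)), k=4)


class TestOplsda:
    def test_zero_orth_matches_pls1_oracle(self):
        cross = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        labels = two_group_labels()
        y = np.array([1.0 if lab == "case" else -1.0 for lab in labels])
        X = rng.normal(size=(13, 40)) + 0.8 * np.outer(y, rng.normal(size=40))
        ours = fit_oplsda(X, labels, n_orth=0, scaling="mean_center")
        ref = cross.PLSRegression(n_components=1, scale=False).fit(X, y)
        t_ref = ref.x_scores_[:, 0]
        sign = np.sign(ours.t_pred @ t_ref)
        assert np.max(np.abs(ours.t_pred * sign - t_ref)) < 1e-8

    def test_single_informative_column_has_unit_correlation(self):
        labels = two_group_labels()
        y = np.array([1.0 if lab == "case" else -1.0 for lab in labels])
        X = np.column_stack([np.ones(13), y * 2.0 + 5.0, np.full(13, 3.0)])
        with pytest.warns(UserWarning):  # zero-variance columns
            model = fit_oplsda(X, labels, n_orth=0)
        assert abs(model.corr_loadings[1]) == pytest.approx(1.0, abs=1e-9)
        assert model.corr_loadings[0] == 0.0 and model.corr_loadings[2] == 0.0

    def test_case_group_mean_score_is_positive(self):
        rng = np.random.default_rng(10)
        labels = two_group_labels()
        y = np.array([1.0 if lab == "case" else -1.0 for lab in labels])
        # informative column pointing *down* in cases: orientation must still
        # put the case mean on the positive side
        X = rng.normal(size=(13, 20)) * 0.1 - 2.0 * np.outer(y, np.eye(20)[0])
        model = fit_oplsda(X, labels)
        case_mean = model.t_pred[np.array(labels) == "case"].mean()
        assert case_mean > 0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        labels = two_group_labels()
        X = rng.normal(size=(13, 25))
        model = fit_oplsda(X, labels)
        perm = rng.permutation(13)
        permuted = fit_oplsda(X[perm], [labels[i] for i in perm])
        np.testing.assert_allclose(permuted.t_pred, model.t_pred[perm], atol=1e-8)
        np.testing.assert_allclose(permuted.corr_loadings, model.corr_loadings,
                                   atol=1e-8)

    def test_orthogonal_filtering_stabilises_predictive_direction(self):
        # appending strong class-unrelated structure must barely rotate the
        # predictive score when one orthogonal component is removed, while the
        # unfiltered PLS direction rotates measurably
        rng = np.random.default_rng(12)
        labels = two_group_labels()
        y = np.array([1.0 if lab == "case" else -1.0 for lab in labels])
        base = 0.05 * rng.normal(size=(13, 20))
        base[:, 0] += y
        u = rng.normal(size=13)
        u -= (u @ y) / (y @ y) * y  # exactly class-orthogonal sample pattern
        u += 0.25 * rng.normal(size=13) * 0.3  # incidental class correlation
        extra = 5.0 * np.outer(u, rng.normal(size=5))
        augmented = np.hstack([base, extra])

        def angle(a, b):
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            return np.degrees(np.arccos(min(cos, 1.0)))

        t_base1 = fit_oplsda(base, labels, n_orth=1).t_pred
        pad = lambda m: m.t_pred
        t_aug1 = pad(fit_oplsda(augmented, labels, n_orth=1))
        t_base0 = fit_oplsda(base, labels, n_orth=0).t_pred
        t_aug0 = pad(fit_oplsda(augmented, labels, n_orth=0))
        assert angle(t_base1, t_aug1) < 5.0
        assert angle(t_base0, t_aug0) > angle(t_base1, t_aug1)

    def test_r2x_and_corr_loading_bounds(self):
        rng = np.random.default_rng(13)
        model = fit_oplsda(rng.normal(size=(13, 30)), two_group_labels())
        assert 0.0 <= model.r2x <= 1.0
        assert np.all(np.abs(model.corr_loadings) <= 1.0)
        assert abs(np.linalg.norm(model.w_pred) - 1.0) < 1e-8
        for j in range(model.n_orth):
            assert abs(np.linalg.norm(model.w_orth[:, j]) - 1.0) < 1e-8
            assert abs(model.w_orth[:, j] @ model.w_pred) < 1e-8

    def test_more_than_two_classes_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 5))
        with pytest.raises(ValueError):
            fit_oplsda(X, ["a", "a", "b", "b", "c", "c"])


class TestCrossValidatedQ2:
    def test_perfectly_predictive_column_scores_high(self):
        rng = np.random.default_rng(14)
        labels = two_group_labels()
        y = np.array([1.0 if lab == "case" else -1.0 for lab in labels])
        X = 0.01 * rng.normal(size=(13, 30))
        X[:, 0] = 10.0 * y
        q2 = cross_validated_q2(X, labels)
        assert q2 > 0.9

    def test_uninformative_matrix_is_nonpositive(self):
        X = np.tile(np.linspace(1.0, 2.0, 12), (13, 1))
        X = X + 0.0  # constant rows: no class information at all
        with pytest.warns(UserWarning):  # zero-variance columns
            q2 = cross_validated_q2(X, two_group_labels())
        assert q2 <= 0.0

    def test_q2_never_exceeds_one(self):
        for seed in range(5):
            X = np.random.default_rng(seed).normal(size=(13, 20))
            assert cross_validated_q2(X, two_group_labels()) <= 1.0

    def test_permuted_labels_mostly_nonpositive(self):
        # anti-overfitting behaviour: with no real class structure the
        # cross-validated predictivity should be negative on average and
        # non-positive in the clear majority of permutations
        rng = np.random.default_rng(16)
        X = rng.normal(size=(13, 100))
        labels = two_group_labels()
        vals = []
        for _ in range(100):
            perm = rng.permutation(13)
            vals.append(cross_validated_q2(X, [labels[i] for i in perm]))
        vals = np.array(vals)
        assert vals.mean() < 0.0
        assert (vals <= 0).mean() >= 0.7

    def test_degenerate_fold_reports_index(self):
        labels = ["case" if i % 2 == 0 else "control" for i in range(13)]
        X = np.random.default_rng(17).normal(size=(13, 10))
        with pytest.raises(DegenerateFoldError, match="fold 0"):
            cross_validated_q2(X, labels, folds=2)

    def test_invalid_fold_count_rejected(self):
        X = np.random.default_rng(18).normal(size=(13, 10))
        with pytest.raises(ValueError):
            cross_validated_q2(X, two_group_labels(), folds=1)
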