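"""PLS engine: NIPALS, Monte Carlo validation, target projection, effects."""

import numpy as np
import pytest

from mvpatrial.pls import (
    BINARY_GROUP_SD,
    ci_widening_factor,
    covariate_project,
    mc_validate,
    pls1_fit,
    resample_effect_cis,
    run_mvpa,
    standardize,
    target_project,
    to_effect_pattern,
)


class TestStandardize:
    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        y = rng.normal(size=20)
        with pytest.warns(UserWarning):
            Xs, ys, params = standardize(X, y)
        assert Xs.shape == (20, 1)
        assert params.dropped == [1]

    def test_columns_scaled_to_unit_variance(self, rng):
        X = rng.normal(5, 9, size=(10, 3))
        y = rng.normal(size=10)
        Xs, ys, _ = standardize(X, y)
        np.testing.assert_allclose(Xs.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1, atol=1e-12)
        assert abs(ys.mean()) < 1e-12


class TestCovariateProject:
    def test_orthogonal_covariate_leaves_x_unchanged(self, rng):
        X = rng.normal(size=(200, 3))
        # covariate exactly orthogonal to the intercept and every X column
        Q, _ = np.linalg.qr(np.column_stack([np.ones(200), X]))
        C = rng.normal(size=200)
        C -= Q @ (Q.T @ C)
        y = rng.normal(size=200)
        Xr, _ = covariate_project(X - X.mean(0), y - y.mean(), C)
        np.testing.assert_allclose(Xr, X - X.mean(0), atol=1e-10)

    def test_column_duplicated_in_covariates_vanishes(self, rng):
        X = rng.normal(size=(50, 3))
        Xr, _ = covariate_project(X, rng.normal(size=50), X[:, [1]])
        np.testing.assert_allclose(Xr[:, 1], 0, atol=1e-10)

    def test_matches_hat_matrix_oracle(self, rng):
        """Sequential rank-one projections equal OLS residualization on [1, C]."""
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        C = rng.normal(size=(60, 2))
        Xr, yr = covariate_project(X, y, C)
        D = np.column_stack([np.ones(60), C])
        H = D @ np.linalg.solve(D.T @ D, D.T)
        np.testing.assert_allclose(Xr, X - H @ X, atol=1e-8)
        np.testing.assert_allclose(yr, y - H @ y, atol=1e-8)
        for k in range(2):
            assert abs(np.corrcoef(yr, C[:, k])[0, 1]) < 1e-8

    def test_degenerate_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            covariate_project(
                rng.normal(size=(20, 2)), rng.normal(size=20), np.full(20, 2.0)
            )


class TestPLS1:
    def test_perfect_single_predictor(self, rng):
        y = rng.normal(size=30)
        y = (y - y.mean()) / y.std(ddof=1)
        model = pls1_fit(y[:, None], y, 1)
        assert model.coef[0] == pytest.approx(1.0)
        assert model.r2(y[:, None], y) == pytest.approx(1.0)

    def test_equals_ols_at_full_rank(self, rng):
        X = rng.normal(size=(40, 6))
        X -= X.mean(0)
        y = rng.normal(size=40)
        y -= y.mean()
        model = pls1_fit(X, y, 6)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(model.coef, b_ols, atol=1e-8)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against scikit-learn's PLS at fewer components."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(50, 8))
        X -= X.mean(0)
        y = X @ rng.normal(size=8) + rng.normal(size=50)
        y -= y.mean()
        for A in (1, 3):
            ours = pls1_fit(X, y, A)
            ref = sklearn_pls.PLSRegression(n_components=A, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.coef, ref.coef_.ravel(), atol=1e-8
            )

    def test_scores_orthogonal_and_x_reconstructed(self, rng):
        X = rng.normal(size=(25, 5))
        X -= X.mean(0)
        y = rng.normal(size=25)
        y -= y.mean()
        model = pls1_fit(X, y, 5)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        np.testing.assert_allclose(
            model.scores @ model.x_loadings.T, X, atol=1e-8
        )

    def test_unpredictive_outcome_gives_tiny_coefficients(self, rng):
        X = rng.normal(size=(500, 4))
        X -= X.mean(0)
        y = rng.normal(size=500)
        y -= y.mean()
        model = pls1_fit(X, y, 2)
        assert model.r2(X, y) < 0.05

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X -= X.mean(0)
        y = rng.normal(size=10)
        with pytest.warns(UserWarning):
            model = pls1_fit(X, y - y.mean(), 8)
        assert model.n_components <= 3


class TestMCValidate:
    def test_pure_noise_not_predictive(self, rng):
        flags = 0
        for s in range(10):
            g = np.random.default_rng(1000 + s)
            X = g.normal(size=(200, 8))
            y = g.normal(size=200)
            v = mc_validate(X, y, A_max=4, reps=100, seed=s)
            flags += v.predictive
        assert flags <= 2  # ~5% false-positive rate under the null

    def test_strong_signal_is_predictive(self, rng):
        X = rng.normal(size=(200, 6))
        y = X @ np.array([1.0, -0.5, 0.3, 0, 0, 0]) + 0.3 * rng.normal(size=200)
        v = mc_validate(X, y, A_max=4, reps=200, seed=0)
        assert v.predictive and v.selected_components >= 1
        assert v.validated_explained_variance_pct > 50

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + rng.normal(size=60)
        v1 = mc_validate(X, y, 3, reps=50, seed=11)
        v2 = mc_validate(X, y, 3, reps=50, seed=11)
        np.testing.assert_array_equal(v1.explained_variance, v2.explained_variance)
        assert v1.selected_components == v2.selected_components

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            mc_validate(rng.normal(size=(5, 2)), rng.normal(size=5), 1)


class TestTargetProjection:
    def test_single_variable_reduces_to_pearson(self, rng):
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(size=80)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        model = pls1_fit(x[:, None], y, 1)
        tp = target_project(model, x[:, None], y)
        assert tp.r[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_duplicated_columns_share_correlation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        X = np.column_stack([x, x])
        X -= X.mean(0)
        y -= y.mean()
        model = pls1_fit(X, y, 1)
        tp = target_project(model, X, y)
        assert tp.r[0] == pytest.approx(tp.r[1], abs=1e-12)

    def test_orthonormal_columns_preserve_ranking(self, rng):
        """|r_j| ranks variables like their bivariate correlations with y."""
        M = rng.normal(size=(120, 5))
        Q, _ = np.linalg.qr(M - M.mean(0))
        X = Q * np.sqrt(120)
        y = X @ np.array([0.8, -0.6, 0.4, 0.2, 0.05]) + rng.normal(size=120)
        y -= y.mean()
        model = pls1_fit(X, y, 1)
        tp = target_project(model, X, y)
        bivar = [np.corrcoef(X[:, j], y)[0, 1] for j in range(5)]
        assert list(np.argsort(np.abs(tp.r))) == list(np.argsort(np.abs(bivar)))

    def test_magnitude_bounded_by_one(self, rng):
        X = rng.normal(size=(50, 7))
        y = X[:, 0] + rng.normal(size=50)
        model = pls1_fit(X - X.mean(0), y - y.mean(), 3)
        tp = target_project(model, X - X.mean(0), y - y.mean())
        assert np.all(np.abs(tp.r) <= 1 + 1e-12)


class TestResampledCIs:
    def test_99_contains_95(self, rng):
        X = rng.normal(size=(150, 4))
        y = X[:, 0] * 0.5 + rng.normal(size=150)
        _, lo95, hi95 = resample_effect_cis(X, y, 1, level=0.95, reps=200, seed=4)
        _, lo99, hi99 = resample_effect_cis(X, y, 1, level=0.99, reps=200, seed=4)
        assert np.all(lo99 <= lo95) and np.all(hi99 >= hi95)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(size=100)
        a = resample_effect_cis(X, y, 1, reps=150, seed=9)
        b = resample_effect_cis(X, y, 1, reps=150, seed=9)
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_array_equal(a[2], b[2])

    def test_null_variable_ci_covers_zero(self, rng):
        X = rng.normal(size=(300, 3))
        y = X[:, 0] + 0.5 * rng.normal(size=300)  # columns 1, 2 are null
        _, lo, hi = resample_effect_cis(X, y, 1, level=0.99, reps=300, seed=2)
        assert lo[1] < 0 < hi[1]
        assert lo[2] < 0 < hi[2]


class TestEffectPattern:
    def test_smd_is_twice_r(self):
        ep = to_effect_pattern(
            ["a"], np.array([0.10]), np.array([0.02]), np.array([0.18]),
            sds=np.array([10.0]),
        )
        row = ep.table.iloc[0]
        assert row["smd"] == pytest.approx(0.20)
        assert row["minutes"] == pytest.approx(2.0)
        assert bool(row["significant"])

    def test_zero_correlation_zero_effect(self):
        ep = to_effect_pattern(
            ["a"], np.array([0.0]), np.array([-0.1]), np.array([0.1]),
            sds=np.array([5.0]),
        )
        assert ep.table["smd"].iloc[0] == 0
        assert ep.table["minutes"].iloc[0] == 0
        assert not ep.table["significant"].iloc[0]

    def test_binary_group_sd_constant(self):
        # SD of a balanced 0/1 group is 0.5 - the SMD conversion denominator
        g = np.array([0, 1] * 50)
        assert g.std() == BINARY_GROUP_SD

    def test_ci_widening_95_to_99(self):
        assert 100 * ci_widening_factor(0.99, 0.95) == pytest.approx(32, abs=1.0)


class TestRunMVPA:
    def test_effect_trial_yields_predictive_model(self, small_trial):
        from mvpatrial.change import build_change_table

        ct = build_change_table(small_trial, "7mo", "ITT")
        res = run_mvpa(ct, reps=200, ci_reps=200, seed=3)
        assert res.validation.predictive
        tab = res.pattern.table.set_index("variable")
        assert tab.loc["sed", "smd"] < 0
        assert tab.loc["lpa", "smd"] > 0

    def test_deterministic_under_seed(self, small_trial):
        from mvpatrial.change import build_change_table

        ct = build_change_table(small_trial, "7mo", "ITT")
        a = run_mvpa(ct, reps=100, ci_reps=150, seed=8)
        b = run_mvpa(ct, reps=100, ci_reps=150, seed=8)
        assert a.validation.selected_components == b.validation.selected_components
        if a.pattern is not None:
            np.testing.assert_array_equal(
                a.pattern.table["r"].to_numpy(), b.pattern.table["r"].to_numpy()
            )
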