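"""Row-wise OLS, the concatenated SVD and the projection estimator."""

import numpy as np
import pytest

from reffree_ewas import (
    DesignMatrix,
    MethylationMatrix,
    concat_and_decompose,
    direct_effects,
    estimate_direct_effects,
    fit_unadjusted,
    impute_loadings_for_incomplete_rows,
    ols_standard_errors,
)

from conftest import make_X, make_Y


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: explicit (XᵀX)⁻¹Xᵀy."""
    return np.linalg.inv(X.T @ X) @ X.T @ y


class TestFitUnadjusted:
    def test_exact_linear_data_recovers_coefficients(self, rng):
        x = rng.uniform(0, 1, size=8)
        X = make_X(x)
        B = np.column_stack([rng.uniform(0.3, 0.7, 5), rng.uniform(-0.1, 0.1, 5)])
        Y = make_Y(B @ X.values.T)
        fit = fit_unadjusted(Y, X)
        np.testing.assert_allclose(fit.coefficients, B, atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle_rowwise(self, rng):
        x = rng.uniform(0, 1, size=12)
        X = make_X(x)
        Y = make_Y(rng.uniform(0, 1, size=(10, 12)))
        fit = fit_unadjusted(Y, X)
        for j in range(10):
            np.testing.assert_allclose(
                fit.coefficients[j],
                normal_equations(X.values, Y.values[j]),
                atol=1e-10,
            )

    def test_masked_sample_fitted_by_complete_case_oracle(self, rng):
        x = rng.uniform(0, 1, size=8)
        X = make_X(x)
        vals = rng.uniform(0.1, 0.9, size=(5, 8))
        vals[2, 3] = np.nan
        fit = fit_unadjusted(make_Y(vals), X)
        obs = np.ones(8, dtype=bool)
        obs[3] = False
        np.testing.assert_allclose(
            fit.coefficients[2],
            normal_equations(X.values[obs], vals[2, obs]),
            atol=1e-10,
        )
        assert not fit.complete_rows[2]
        assert np.isnan(fit.residuals[2, 3])
        # fitted means materialised even at the missing position
        assert np.isfinite(fit.fitted_means[2, 3])

    def test_residuals_orthogonal_to_design(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        np.testing.assert_allclose(fit.residuals @ X.values, 0.0, atol=1e-10)

    def test_too_few_observed_samples_raises(self, rng):
        x = rng.uniform(0, 1, size=5)
        X = make_X(x)
        vals = rng.uniform(0.1, 0.9, size=(3, 5))
        vals[0, :3] = np.nan  # 2 observed < p+1 = 3
        with pytest.raises(ValueError, match="observed samples"):
            fit_unadjusted(make_Y(vals), X)

    def test_rank_deficient_design_raises(self):
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(
                values=np.column_stack([np.ones(6), np.ones(6)]),
                column_names=["intercept", "const"],
            )

    def test_rank_deficiency_on_observed_subset_raises(self):
        # binary covariate whose only "1" sample is missing for one row
        x = np.array([0.0, 0, 0, 0, 0, 1])
        X = make_X(x)
        vals = np.full((2, 6), 0.5)
        vals[0, 5] = np.nan
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_unadjusted(make_Y(vals), X)


class TestConcatAndDecompose:
    def test_d_zero_gives_empty_basis_and_identity_projection(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 0)
        assert decomp.loadings.shape == (10, 0)
        est = direct_effects(fit, decomp)
        np.testing.assert_array_equal(est.direct_effects, fit.coefficients)

    def test_exact_rank_two_matrix_reconstructs(self, rng):
        # plant rank-2 structure in Y so [B|E] is (numerically) low rank
        x = rng.uniform(0, 1, size=20)
        X = make_X(x)
        u = rng.normal(size=(30, 2))
        vB = rng.normal(size=(2, 2))
        vE = rng.normal(size=(2, 20))
        fitB = u @ vB
        # residual factor must be orthogonal to the design for consistency
        P = np.eye(20) - X.values @ np.linalg.inv(X.values.T @ X.values) @ X.values.T
        fitE = u @ vE @ P
        Y = make_Y(fitB @ X.values.T + fitE)
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 2)
        Z = np.hstack([fit.coefficients, fit.residuals])
        np.testing.assert_allclose(
            decomp.loadings @ decomp.factors.T, Z, atol=1e-8
        )
        full_s = np.linalg.svd(Z, compute_uv=False)
        assert full_s[2] < 1e-8 * full_s[0]

    def test_truncation_matches_full_svd_oracle(self, rng):
        x = rng.uniform(0, 1, size=20)
        X = make_X(x)
        Y = make_Y(rng.uniform(0, 1, size=(50, 20)))
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 3)
        Z = np.hstack([fit.coefficients, fit.residuals])
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        best3 = (U[:, :3] * s[:3]) @ Vt[:3]
        err_ours = np.linalg.norm(Z - decomp.loadings @ decomp.factors.T)
        err_oracle = np.linalg.norm(Z - best3)
        assert abs(err_ours - err_oracle) < 1e-10
        assert np.all(np.diff(decomp.singular_values) <= 0)

    def test_d_exceeding_rank_raises(self, rng):
        # [B|E] has rank <= p + (n - p) = n; ask for one more
        x = rng.uniform(0, 1, size=12)
        X = make_X(x)
        Y = make_Y(rng.uniform(0.1, 0.9, size=(30, 12)))
        fit = fit_unadjusted(Y, X)
        with pytest.raises(ValueError, match="rank"):
            concat_and_decompose(fit, 13)

    def test_loading_columns_orthogonal(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 3)
        gram = decomp.loadings.T @ decomp.loadings
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)


class TestImputeLoadings:
    def test_planted_noiseless_row_recovered(self, rng):
        x = rng.uniform(0, 1, size=10)
        X = make_X(x)
        vals = rng.uniform(0.2, 0.8, size=(20, 10))
        fit = fit_unadjusted(make_Y(vals), X)
        decomp = concat_and_decompose(fit, 2)
        # forge an incomplete row whose observed entries equal lam @ F.T
        lam = np.array([0.3, -0.8])
        vals2 = np.vstack([vals.copy(), np.full(10, 0.5)])
        Y2 = make_Y(vals2)
        Y2.values[20, 4] = np.nan
        fit2 = fit_unadjusted(Y2, X)
        decomp2 = concat_and_decompose(fit2, 2)
        Z2 = np.hstack([fit2.coefficients, fit2.residuals])
        Z2[20] = lam @ decomp2.factors.T
        Z2[20, 2 + 4] = np.nan
        fit2.coefficients[20] = Z2[20, :2]
        fit2.residuals[20] = Z2[20, 2:]
        full = impute_loadings_for_incomplete_rows(fit2, decomp2)
        np.testing.assert_allclose(full.loadings[20], lam, atol=1e-8)
        assert full.rows_used.all()

    def test_complete_row_regression_reproduces_svd_loading(self, rng):
        x = rng.uniform(0, 1, size=10)
        X = make_X(x)
        vals = rng.uniform(0.2, 0.8, size=(20, 10))
        fit = fit_unadjusted(make_Y(vals), X)
        decomp = concat_and_decompose(fit, 3)
        Z = np.hstack([fit.coefficients, fit.residuals])
        # regression on the orthonormal factor basis == the SVD loading
        for j in (0, 7, 19):
            lam, *_ = np.linalg.lstsq(decomp.factors, Z[j], rcond=None)
            np.testing.assert_allclose(lam, decomp.loadings[j], atol=1e-9)

    def test_saturated_regression_interpolates(self, rng):
        # exactly d observed concatenated entries -> interpolating fit
        x = rng.uniform(0, 1, size=6)
        X = make_X(x)
        vals = rng.uniform(0.2, 0.8, size=(15, 6))
        vals[3, 3:] = np.nan  # 3 observed samples = p+1; 2+3 = 5 entries
        fit = fit_unadjusted(make_Y(vals), X)
        decomp = concat_and_decompose(fit, 5)
        full = impute_loadings_for_incomplete_rows(fit, decomp)
        Z = np.hstack([fit.coefficients, fit.residuals])
        obs = ~np.isnan(Z[3])
        assert obs.sum() == 5
        resid = Z[3, obs] - full.loadings[3] @ decomp.factors[obs].T
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)


class TestDirectEffects:
    def test_full_absorption_inside_span(self, rng):
        L = rng.normal(size=(30, 3))
        B = L @ rng.normal(size=(3, 2))
        est = _project(B, L)
        np.testing.assert_allclose(est, 0.0, atol=1e-10)

    def test_matches_least_squares_residual_oracle(self, rng):
        L = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 2))
        est = _project(B, L)
        for c in range(2):
            coef, *_ = np.linalg.lstsq(L, B[:, c], rcond=None)
            np.testing.assert_allclose(est[:, c], B[:, c] - L @ coef, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_to_invertible_recombination(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 2))
        R = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        np.testing.assert_allclose(_project(B, L), _project(B, L @ R), atol=1e-10)

    def test_projection_decomposition_identity(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 3)
        est = direct_effects(fit, decomp)
        L = decomp.loadings
        proj = L @ np.linalg.solve(L.T @ L, L.T @ fit.coefficients)
        np.testing.assert_allclose(
            est.direct_effects + proj, fit.coefficients, atol=1e-8
        )

    def test_projection_idempotent(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 3)
        est = direct_effects(fit, decomp)
        again = _project(est.direct_effects, decomp.loadings)
        np.testing.assert_allclose(again, est.direct_effects, atol=1e-10)

    def test_collinear_loadings_raise(self, small_dataset):
        Y, X, _, _ = small_dataset
        fit = fit_unadjusted(Y, X)
        decomp = concat_and_decompose(fit, 2)
        decomp.loadings[:, 1] = 2.0 * decomp.loadings[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            direct_effects(fit, decomp)

    def test_full_rank_basis_absorbs_everything(self, rng):
        # with a basis containing B's column space, the direct effect -> 0
        x = rng.uniform(0, 1, size=20)
        X = make_X(x)
        Y = make_Y(rng.uniform(0.1, 0.9, size=(15, 20)))
        fit = fit_unadjusted(Y, X)
        Z = np.hstack([fit.coefficients, fit.residuals])
        rank = np.linalg.matrix_rank(Z)
        decomp = concat_and_decompose(fit, rank)
        est = direct_effects(fit, decomp)
        np.testing.assert_allclose(est.direct_effects, 0.0, atol=1e-8)

    def test_oracle_equivalence_dense_recomputation(self, rng):
        """Every pipeline step matches a brute-force dense recomputation."""
        x = rng.uniform(0, 1, size=20)
        X = make_X(x)
        Y = make_Y(rng.uniform(0.1, 0.9, size=(50, 20)))
        fit, decomp, est = estimate_direct_effects(Y, X, 4)
        B_o = (np.linalg.inv(X.values.T @ X.values) @ X.values.T @ Y.values.T).T
        E_o = Y.values - B_o @ X.values.T
        Z = np.hstack([B_o, E_o])
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        L = U[:, :4] * s[:4]
        D_o = B_o - L @ np.linalg.inv(L.T @ L) @ L.T @ B_o
        np.testing.assert_allclose(fit.coefficients, B_o, atol=1e-9)
        np.testing.assert_allclose(est.direct_effects, D_o, atol=1e-8)


def _project(B: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Run the package's projection on a bare (B, Λ) pair."""
    from reffree_ewas.linear_core import (
        DirectEffectEstimate,
        LatentDecomposition,
        UnadjustedFit,
    )

    m = B.shape[0]
    fit = UnadjustedFit(
        coefficients=B,
        residuals=np.zeros((m, 1)),
        fitted_means=np.zeros((m, 1)),
        complete_rows=np.ones(m, dtype=bool),
        design=None,
    )
    decomp = LatentDecomposition(
        loadings=L,
        factors=np.zeros((1, L.shape[1])),
        singular_values=np.zeros(L.shape[1]),
        d=L.shape[1],
        rows_used=np.ones(m, dtype=bool),
    )
    return direct_effects(fit, decomp).direct_effects


def test_ols_standard_errors_match_closed_form(rng):
    x = rng.uniform(0, 1, size=30)
    X = make_X(x)
    Y = make_Y(rng.uniform(0.1, 0.9, size=(8, 30)))
    fit = fit_unadjusted(Y, X)
    se = ols_standard_errors(fit)
    XtXinv = np.linalg.inv(X.values.T @ X.values)
    for j in range(8):
        s2 = fit.residuals[j] @ fit.residuals[j] / (30 - 2)
        np.testing.assert_allclose(se[j], np.sqrt(s2 * np.diag(XtXinv)), atol=1e-12)


def test_beta_range_validation():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        MethylationMatrix(
            values=np.array([[0.5, 1.2]]), cpg_ids=["a"], sample_ids=["s1", "s2"]
        )
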