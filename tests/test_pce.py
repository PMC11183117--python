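"""Polynomial chaos basis, fitting, and model-selection tests."""

import numpy as np
import pytest

from trajgsa.exceptions import (
    DegenerateResponseError,
    IllConditionedProblemError,
)
from trajgsa.pce import (
    Marginal,
    PCESurrogate,
    evaluate_basis,
    fit_surrogate,
    hybrid_lar_fit,
    loo_error,
    ols_fit,
    total_degree_multiindices,
    validation_metrics,
)

UNIT = (Marginal.uniform(0.0, 1.0, "x1"), Marginal.uniform(0.0, 1.0, "x2"))


class TestMultiIndices:
    @pytest.mark.parametrize(
        "k,s_max,expected",
        [
            (1, 2, ((0,), (1,), (2,))),
            (2, 1, ((0, 0), (1, 0), (0, 1))),
        ],
    )
    def test_small_sets_graded_lex(self, k, s_max, expected):
        assert total_degree_multiindices(k, s_max).indices == expected

    def test_cardinality_formula(self):
        # (k + s_max)! / (k! s_max!) instantiated at k=2, s_max=6
        assert len(total_degree_multiindices(2, 6)) == 28

    def test_contains_zero_and_degree_bound(self):
        basis = total_degree_multiindices(3, 4)
        assert (0, 0, 0) in basis.indices
        assert all(sum(s) <= 4 for s in basis.indices)


class TestBasisEvaluation:
    def test_zero_tuple_column_is_one(self, rng):
        basis = total_degree_multiindices(2, 3)
        X = rng.random((50, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        np.testing.assert_array_equal(Phi[:, 0], 1.0)

    def test_degree_one_legendre_values(self):
        # psi_1(x) = sqrt(3) (2x - 1) for U(0, 1); zero at the midpoint.
        basis = total_degree_multiindices(1, 1)
        marg = (Marginal.uniform(0.0, 1.0),)
        X = np.array([[0.5], [0.25], [1.0]])
        Phi = evaluate_basis(X, basis, marg)
        np.testing.assert_allclose(
            Phi[:, 1], np.sqrt(3.0) * np.array([0.0, -0.5, 1.0]), atol=1e-12
        )

    def test_mc_gram_identity(self):
        # MC orthonormality oracle: 1e6 samples, k=2, s_max=3.
        rng = np.random.default_rng(7)
        basis = total_degree_multiindices(2, 3)
        X = rng.random((10**6, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        G = (Phi.T @ Phi) / Phi.shape[0]
        np.testing.assert_allclose(G, np.eye(len(basis)), atol=5e-3)

    def test_quadrature_orthonormality_both_families(self):
        # Gauss quadrature oracle for univariate families up to degree 10.
        from numpy.polynomial.hermite_e import hermegauss
        from numpy.polynomial.legendre import leggauss

        deg = 10
        basis = total_degree_multiindices(1, deg)
        xg, wg = leggauss(2 * deg + 2)
        Phi = evaluate_basis(
            xg[:, None], basis, (Marginal.uniform(-1.0, 1.0),)
        )
        G = (Phi * (wg / 2.0)[:, None]).T @ Phi
        np.testing.assert_allclose(G, np.eye(deg + 1), atol=1e-10)

        xg, wg = hermegauss(2 * deg + 2)
        Phi = evaluate_basis(xg[:, None], basis, (Marginal.normal(0.0, 1.0),))
        G = (Phi * (wg / np.sqrt(2 * np.pi))[:, None]).T @ Phi
        np.testing.assert_allclose(G, np.eye(deg + 1), atol=1e-8)

    def test_nonunit_uniform_bounds_are_standardized(self, rng):
        # Same standardized abscissae -> same basis values regardless of the
        # declared interval.
        basis = total_degree_multiindices(1, 4)
        x = rng.uniform(1.9, 6.5, 100)[:, None]
        Phi_a = evaluate_basis(x, basis, (Marginal.uniform(1.9, 6.5),))
        z = (2.0 * (x - 1.9) / (6.5 - 1.9) - 1.0 + 1.0) / 2.0  # to [0, 1]
        Phi_b = evaluate_basis(z, basis, (Marginal.uniform(0.0, 1.0),))
        np.testing.assert_allclose(Phi_a, Phi_b, atol=1e-12)


class TestOLSAndLOO:
    def test_exact_basis_column_response(self, rng):
        basis = total_degree_multiindices(2, 3)
        X = rng.random((60, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        j = basis.position((1, 1))
        coef, eps = ols_fit(Phi, Phi[:, j])
        expected = np.zeros(len(basis))
        expected[j] = 1.0
        np.testing.assert_allclose(coef, expected, atol=1e-10)
        assert eps[0] < 1e-10

    def test_residual_orthogonality(self, rng):
        Phi = rng.standard_normal((80, 12))
        y = rng.standard_normal(80)
        coef, _ = ols_fit(Phi, y)
        r = y - Phi @ coef
        assert np.max(np.abs(Phi.T @ r)) < 1e-8

    def test_loo_matches_explicit_refits(self, rng):
        # Oracle: N refits each omitting one sample.
        N, P = 40, 10
        Phi = rng.standard_normal((N, P))
        y = rng.standard_normal(N)
        coef, eps = ols_fit(Phi, y)
        sq = []
        for i in range(N):
            keep = np.arange(N) != i
            ci, *_ = np.linalg.lstsq(Phi[keep], y[keep], rcond=None)
            sq.append((y[i] - Phi[i] @ ci) ** 2)
        brute = np.mean(sq) / np.var(y, ddof=1)
        assert eps[0] == pytest.approx(brute, abs=1e-8)
        assert loo_error(Phi, y, coef)[0] == pytest.approx(brute, abs=1e-8)

    def test_polynomial_exactness(self, rng):
        # OLS with s_max >= deg(f) and N >= P recovers any polynomial response.
        basis = total_degree_multiindices(2, 4)
        X = rng.random((120, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        truth = rng.standard_normal(len(basis))
        coef, eps = ols_fit(Phi, Phi @ truth)
        np.testing.assert_allclose(coef, truth, atol=1e-8)
        assert eps[0] < 1e-10

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(IllConditionedProblemError):
            ols_fit(rng.standard_normal((5, 8)), rng.standard_normal(5))

    def test_constant_response_degenerate(self, rng):
        Phi = rng.standard_normal((20, 3))
        with pytest.raises(DegenerateResponseError):
            ols_fit(Phi, np.ones(20))


class TestHybridLAR:
    def test_planted_sparse_recovery(self, rng):
        basis = total_degree_multiindices(2, 6)
        X = rng.random((200, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        i20, i01 = basis.position((2, 0)), basis.position((0, 1))
        y = 2.0 * Phi[:, i20] + 0.5 * Phi[:, i01]
        cols, coef, path = hybrid_lar_fit(Phi, y, constant_index=0)
        assert {i20, i01} <= set(cols.tolist())
        assert coef[i20] == pytest.approx(2.0, abs=1e-6)
        assert coef[i01] == pytest.approx(0.5, abs=1e-6)
        assert min(path) < 1e-10

    def test_first_step_selects_most_correlated(self, rng):
        basis = total_degree_multiindices(2, 4)
        X = rng.random((150, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        j = basis.position((3, 0))
        cols, coef, _ = hybrid_lar_fit(Phi, Phi[:, j], constant_index=0)
        assert cols[1] == j  # first active predictor after the constant
        assert coef[j] == pytest.approx(1.0, abs=1e-8)

    def test_active_set_size_bounded(self, rng):
        basis = total_degree_multiindices(2, 8)  # P = 45 > N
        X = rng.random((30, 2))
        Phi = evaluate_basis(X, basis, UNIT)
        y = rng.standard_normal(30)
        cols, _, _ = hybrid_lar_fit(Phi, y, constant_index=0)
        assert len(cols) <= 30

    def test_constant_response_degenerate(self, rng):
        Phi = evaluate_basis(
            rng.random((30, 2)), total_degree_multiindices(2, 2), UNIT
        )
        with pytest.raises(DegenerateResponseError):
            hybrid_lar_fit(Phi, np.full(30, 3.0))

    def test_sparsity_helps_or_matches_ols(self, rng):
        # On sparse truths + noise, the selected model's LOO error beats or
        # matches the full OLS fit in >= 90% of trials.
        basis = total_degree_multiindices(2, 5)
        wins = 0
        trials = 20
        for _ in range(trials):
            X = rng.random((80, 2))
            Phi = evaluate_basis(X, basis, UNIT)
            active = rng.choice(np.arange(1, len(basis)), 3, replace=False)
            y = Phi[:, active] @ rng.standard_normal(3)
            y = y + 0.05 * rng.standard_normal(80)
            _, _, path = hybrid_lar_fit(Phi, y, constant_index=0)
            _, eps_ols = ols_fit(Phi, y)
            if min(path) <= eps_ols[0] * (1 + 1e-12):
                wins += 1
        assert wins >= 0.9 * trials


class TestSurrogate:
    def test_mean_and_variance_identities(self, rng):
        # Eq.-style moment identities: MC mean matches c_0 and MC variance
        # matches the sum of squared non-constant coefficients within 3 SE.
        X = rng.random((300, 2))
        y = 1.5 + np.sin(2 * np.pi * X[:, 0]) + X[:, 1] ** 2
        surr = fit_surrogate(X, y, UNIT, s_max=8, method="ols")
        Xmc = rng.random((10**6, 2))
        pred = surr.predict(Xmc)[:, 0]
        se_mean = pred.std() / 1000.0
        assert surr.mean[0] == pytest.approx(pred.mean(), abs=3 * se_mean)
        var_mc = pred.var(ddof=1)
        se_var = np.sqrt(np.var((pred - pred.mean()) ** 2, ddof=1) / 10**6)
        assert surr.variance[0] == pytest.approx(var_mc, abs=3 * se_var)

    def test_lar_active_sets_per_output(self, rng):
        X = rng.random((150, 2))
        basis = total_degree_multiindices(2, 4)
        Phi = evaluate_basis(X, basis, UNIT)
        Theta = np.column_stack(
            [Phi[:, basis.position((2, 0))], Phi[:, basis.position((0, 1))]]
        )
        surr = fit_surrogate(X, Theta, UNIT, s_max=4, method="lar")
        assert surr.coefficients.shape == (len(basis), 2)
        assert (2, 0) in surr.active_sets[0]
        assert (0, 1) in surr.active_sets[1]

    def test_json_round_trip_bit_exact(self, tmp_path, rng):
        X = rng.random((60, 2))
        y = X[:, 0] + 0.3 * X[:, 1] ** 2
        surr = fit_surrogate(X, y, UNIT, s_max=3, method="lar")
        path = tmp_path / "surrogate.json"
        surr.to_json(path)
        back = PCESurrogate.from_json(path)
        assert np.array_equal(back.coefficients, surr.coefficients)
        assert back.basis == surr.basis
        assert back.marginals == surr.marginals
        assert back.active_sets == surr.active_sets
        np.testing.assert_array_equal(
            back.errors["eps_loo"], surr.errors["eps_loo"]
        )


class TestValidationMetrics:
    def test_exact_surrogate_zero_errors(self, rng):
        X = rng.random((90, 2))
        basis = total_degree_multiindices(2, 3)
        Phi = evaluate_basis(X, basis, UNIT)
        y = Phi[:, 2] * 1.2
        surr = fit_surrogate(X[:60], y[:60], UNIT, s_max=3, method="ols")
        eps_val, mae = validation_metrics(surr, X[60:], y[60:])
        assert eps_val[0] == pytest.approx(0.0, abs=1e-12)
        assert mae[0] == pytest.approx(0.0, abs=1e-8)

    def test_constant_mean_prediction_gives_one(self, rng):
        # A surrogate predicting the test mean scores eps_val = 1 exactly.
        X_test = rng.random((50, 2))
        y_test = rng.standard_normal(50)
        basis = total_degree_multiindices(2, 1)
        coef = np.zeros(len(basis))
        coef[0] = y_test.mean()
        surr = PCESurrogate(basis=basis, coefficients=coef, marginals=UNIT)
        eps_val, mae = validation_metrics(surr, X_test, y_test)
        assert eps_val[0] == pytest.approx(1.0, abs=1e-12)
        assert mae[0] == pytest.approx(
            np.mean(np.abs(y_test - y_test.mean())), abs=1e-12
        )

    def test_matches_independent_reimplementation(self, rng):
        # Re-implementation oracle computed inline from the definitions.
        X = rng.random((40, 2))
        Theta = rng.standard_normal((40, 2))
        surr = fit_surrogate(
            rng.random((60, 2)), rng.standard_normal((60, 2)), UNIT,
            s_max=2, method="ols",
        )
        eps_val, mae = validation_metrics(surr, X, Theta)
        pred = surr.predict(X)
        ref_eps = ((Theta - pred) ** 2).sum(0) / (
            (Theta - Theta.mean(0)) ** 2
        ).sum(0)
        ref_mae = np.abs(Theta - pred).mean(0)
        np.testing.assert_allclose(eps_val, ref_eps, atol=1e-12)
        np.testing.assert_allclose(mae, ref_mae, atol=1e-12)

    def test_zero_test_variance_degenerate(self, rng):
        surr = fit_surrogate(
            rng.random((30, 2)), rng.standard_normal(30), UNIT,
            s_max=1, method="ols",
        )
        with pytest.raises(DegenerateResponseError):
            validation_metrics(surr, rng.random((10, 2)), np.ones(10))
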