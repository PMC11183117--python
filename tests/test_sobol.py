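"""Sobol' index estimation tests: analytic PCE path and Saltelli MC path."""

import itertools
import warnings

import numpy as np
import pytest

from trajgsa.exceptions import DegenerateVarianceError, InvalidInputError
from trajgsa.pce import Marginal, PCESurrogate, fit_surrogate, total_degree_multiindices
from trajgsa.sobol import (
    bootstrap_ci,
    mc_sobol_estimates,
    pce_sobol_indices,
    saltelli_design,
    subset_sobol_index,
)

UNIT2 = (Marginal.uniform(0.0, 1.0, "x1"), Marginal.uniform(0.0, 1.0, "x2"))


def surrogate_from_coeffs(k, s_max, coeffs: dict):
    basis = total_degree_multiindices(k, s_max)
    c = np.zeros(len(basis))
    for s, v in coeffs.items():
        c[basis.position(s)] = v
    marg = tuple(Marginal.uniform(0.0, 1.0, f"x{i+1}") for i in range(k))
    return PCESurrogate(basis=basis, coefficients=c, marginals=marg)


class TestPCEIndices:
    def test_pure_main_effect(self):
        surr = surrogate_from_coeffs(2, 2, {(1, 0): 1.0})
        res = pce_sobol_indices(surr)
        np.testing.assert_allclose(res.first_order[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(res.total_order[:, 0], [1.0, 0.0])

    def test_pure_interaction(self):
        surr = surrogate_from_coeffs(2, 2, {(1, 1): 1.0})
        res = pce_sobol_indices(surr)
        np.testing.assert_allclose(res.first_order[:, 0], [0.0, 0.0])
        np.testing.assert_allclose(res.total_order[:, 0], [1.0, 1.0])

    def test_additive_surrogate_identities(self, rng):
        # No mixed multi-indices: S_i = S_Ti exactly and sum S_i = 1.
        surr = surrogate_from_coeffs(
            2, 3, {(1, 0): 0.7, (2, 0): 0.2, (0, 1): -0.4, (0, 3): 0.1,
                   (0, 0): 5.0}
        )
        res = pce_sobol_indices(surr)
        np.testing.assert_allclose(res.first_order, res.total_order, atol=1e-14)
        assert res.first_order[:, 0].sum() == pytest.approx(1.0, abs=1e-14)
        assert np.all(res.first_order >= 0) and np.all(res.first_order <= 1)

    def test_mixed_coefficient_monotonicity(self):
        base = {(1, 0): 0.8, (0, 1): 0.6}
        r0 = pce_sobol_indices(surrogate_from_coeffs(2, 3, base))
        r1 = pce_sobol_indices(
            surrogate_from_coeffs(2, 3, {**base, (1, 2): 0.5})
        )
        assert np.all(r1.total_order > r0.total_order - 1e-14)
        assert np.all(r1.first_order <= r0.first_order + 1e-14)
        assert np.all(r1.first_order <= r1.total_order + 1e-14)

    def test_subset_decomposition_completeness(self, rng):
        # Sum of S_u over all nonempty subsets u equals 1 for any surrogate.
        basis = total_degree_multiindices(3, 3)
        c = rng.standard_normal(len(basis))
        marg = tuple(Marginal.uniform(0, 1, f"x{i}") for i in range(3))
        surr = PCESurrogate(basis=basis, coefficients=c, marginals=marg)
        total = 0.0
        for r in range(1, 4):
            for u in itertools.combinations(range(3), r):
                total += subset_sobol_index(surr, u)[0]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_coefficients(self):
        surr = surrogate_from_coeffs(2, 2, {(0, 0): 3.0})
        with pytest.raises(DegenerateVarianceError):
            pce_sobol_indices(surr)

    def test_tidy_export(self, tmp_path):
        surr = surrogate_from_coeffs(2, 2, {(1, 0): 1.0, (0, 1): 2.0})
        res = pce_sobol_indices(surr)
        out = tmp_path / "indices.csv"
        res.to_csv(out)
        frame = res.to_frame()
        assert set(frame.columns) >= {"method", "parameter", "output_dim",
                                      "S1", "ST"}
        assert len(frame) == 2


class TestSaltelliDesign:
    def test_paper_scale_row_count(self):
        assert saltelli_design(1024, 5, seed=0).n_rows == 7168

    def test_small_row_count(self):
        design = saltelli_design(4, 2, seed=0)
        assert design.X.shape == (16, 2)

    def test_mixed_block_structure(self):
        design = saltelli_design(16, 3, seed=1)
        N, d = design.N_base, design.d
        A, B = design.X[:N], design.X[N:2 * N]
        for i in range(d):
            AB = design.X[(2 + i) * N:(3 + i) * N]
            np.testing.assert_array_equal(AB[:, i], A[:, i])
            others = [j for j in range(d) if j != i]
            np.testing.assert_array_equal(AB[:, others], B[:, others])

    def test_seed_determinism(self):
        d1 = saltelli_design(32, 2, seed=5)
        d2 = saltelli_design(32, 2, seed=5)
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_invalid_sizes(self):
        with pytest.raises(InvalidInputError):
            saltelli_design(1, 2)


class TestMCEstimates:
    def test_additive_model_analytic_variances(self):
        # Y = X1 + 2 X2 on U(0,1)^2: V_i = b_i^2 / 12, S = (0.2, 0.8),
        # and no interactions so S_Ti ~ S_i.
        design = saltelli_design(2**14, 2, seed=3)
        y = design.X[:, 0] + 2.0 * design.X[:, 1]
        res = mc_sobol_estimates(y, design)
        np.testing.assert_allclose(res.first_order[:, 0], [0.2, 0.8], atol=0.02)
        np.testing.assert_allclose(res.total_order[:, 0], [0.2, 0.8], atol=0.02)

    def test_jansen_variant_agrees(self):
        design = saltelli_design(2**13, 2, seed=9)
        y = design.X[:, 0] + 2.0 * design.X[:, 1]
        res = mc_sobol_estimates(y, design, estimator="jansen")
        np.testing.assert_allclose(res.first_order[:, 0], [0.2, 0.8], atol=0.02)
        np.testing.assert_allclose(res.total_order[:, 0], [0.2, 0.8], atol=0.02)

    def test_constant_output_degenerate(self):
        design = saltelli_design(64, 2, seed=0)
        with pytest.raises(DegenerateVarianceError):
            mc_sobol_estimates(np.full(design.n_rows, 2.5), design)

    def test_ishigami_cross_method_consistency(self, ishigami_problem):
        # MC indices agree with PCE-based indices within 0.03.
        fn, _ = ishigami_problem
        marg = tuple(Marginal.uniform(-np.pi, np.pi, f"x{i+1}")
                     for i in range(3))
        design = saltelli_design(2**15, 3, seed=11)
        X = np.column_stack([m.ppf(design.X[:, j])
                             for j, m in enumerate(marg)])
        res_mc = mc_sobol_estimates(fn(X), design)

        from trajgsa.pipeline import sample_design

        train = sample_design(marg, 1000, seed=4)
        surr = fit_surrogate(train.X, fn(train.X), marg, s_max=9, method="ols")
        res_pce = pce_sobol_indices(surr)
        np.testing.assert_allclose(
            res_mc.first_order, res_pce.first_order, atol=0.03
        )
        np.testing.assert_allclose(
            res_mc.total_order, res_pce.total_order, atol=0.03
        )

    def test_negative_estimates_warn_unclipped(self):
        # A null parameter at small N yields negative estimates; they must
        # be reported as-is.
        design = saltelli_design(64, 2, sampler="pseudorandom", seed=2)
        y = design.X[:, 1] ** 2
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = mc_sobol_estimates(y, design)
        assert res.first_order.min() < 0
        assert any("negative" in str(w.message) for w in caught)

    def test_vector_output_per_component(self):
        design = saltelli_design(2**12, 2, seed=6)
        Y = np.column_stack(
            [design.X[:, 0] + 2 * design.X[:, 1], 3 * design.X[:, 0]]
        )
        res = mc_sobol_estimates(Y, design)
        assert res.first_order.shape == (2, 2)
        np.testing.assert_allclose(res.first_order[:, 0], [0.2, 0.8], atol=0.03)
        np.testing.assert_allclose(res.first_order[:, 1], [1.0, 0.0], atol=0.03)


class TestBootstrap:
    def test_seed_determinism(self):
        design = saltelli_design(256, 2, seed=0)
        y = design.X[:, 0] + 2.0 * design.X[:, 1]
        ci1 = bootstrap_ci(y, design, B=200, seed=42)
        ci2 = bootstrap_ci(y, design, B=200, seed=42)
        for key in ("S1_lo", "S1_hi", "ST_lo", "ST_hi"):
            np.testing.assert_array_equal(ci1[key], ci2[key])

    def test_minimum_resamples_enforced(self):
        design = saltelli_design(64, 2, seed=0)
        y = design.X.sum(axis=1)
        with pytest.raises(InvalidInputError):
            bootstrap_ci(y, design, B=50)

    def test_additive_model_coverage(self):
        # Coverage experiment: the 95% CI for S1 covers the analytic 0.2 in
        # about 95% of outer replications (binomial 3-sigma band).
        reps = 120
        hits = 0
        for r in range(reps):
            design = saltelli_design(
                512, 2, sampler="pseudorandom", seed=1000 + r
            )
            y = design.X[:, 0] + 2.0 * design.X[:, 1]
            ci = bootstrap_ci(y, design, B=200, seed=r)
            if ci["S1_lo"][0, 0] <= 0.2 <= ci["S1_hi"][0, 0]:
                hits += 1
        rate = hits / reps
        sigma = np.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) < 3 * sigma + 0.01
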