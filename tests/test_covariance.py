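"""Covariance engine: constraint resolution, implied moments, the
two-step reduction and local identification."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import compositesem as cs
from compositesem.covariance import CompiledTable, _random_admissible
from compositesem.table import AffineExpr, ParamRow, ParameterTable

IV = {"cover": 1.0, "colf": 1.0}


class TestResolveConstraints:
    def test_effects_coded_third_loading(self, spec):
        table = cs.build_ho_specification(spec, "free", indicator_variances=IV)
        compiled = CompiledTable(table)
        theta = np.zeros(table.q)
        theta[list(compiled.labels).index("l_mois_Soil")] = 0.2
        theta[list(compiled.labels).index("l_pH_Soil")] = 0.3
        A, _, _ = cs.resolve_constraints(table, theta)
        i, j = compiled.index["text"], compiled.index["Soil"]
        assert A[i, j] == pytest.approx(1.0 - 0.2 - 0.3)

    def test_unit_variant_excrescent_pair_sums_to_zero(self, spec):
        table = cs.build_ho_specification(spec, "unit", indicator_variances=IV)
        compiled = CompiledTable(table)
        A, _, _ = cs.resolve_constraints(table, np.zeros(table.q))
        nu = compiled.index["Soil_nu1"]
        loadings = A[:, nu][A[:, nu] != 0]
        assert sorted(loadings) == [-1.0, 1.0]
        assert loadings.sum() == 0.0

    def test_all_fixed_table_accepts_empty_theta(self):
        table = ParameterTable(
            variables=("a",),
            observed=("a",),
            rows=[ParamRow("a", "a", "variance", "fixed", value=2.0)],
        )
        _, Psi, _ = cs.resolve_constraints(table, np.array([]))
        assert Psi[0, 0] == 2.0

    def test_wrong_theta_length_rejected(self, spec):
        table = cs.build_ho_specification(spec, "free", indicator_variances=IV)
        with pytest.raises(cs.exceptions.InputError):
            cs.resolve_constraints(table, np.zeros(3))


class TestImpliedCovariance:
    def test_identity(self):
        eye = np.eye(4)
        np.testing.assert_allclose(
            cs.implied_covariance(np.zeros((4, 4)), eye, eye), eye
        )

    def test_path_tracing_single_regression(self):
        # y = b x, var(x) = phi, disturbance psi: var(y) = b^2 phi + psi
        b, phi, psi = 0.7, 2.0, 0.5
        B = np.array([[0.0, 0.0], [b, 0.0]])
        Psi = np.diag([phi, psi])
        Sigma = cs.implied_covariance(B, Psi, np.eye(2))
        assert Sigma[1, 1] == pytest.approx(b * b * phi + psi)
        assert Sigma[0, 1] == pytest.approx(b * phi)

    def test_cyclic_coefficients_error(self):
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(cs.exceptions.CyclicModelError):
            cs.implied_covariance(B, np.eye(2), np.eye(2))

    def test_symmetry_at_random_admissible_points(self, spec):
        table = cs.build_ho_specification(spec, "relaxed", indicator_variances=IV)
        compiled = CompiledTable(table)
        rng = np.random.default_rng(5)
        for _ in range(20):
            sigma = compiled.sigma(_random_admissible(compiled, rng))
            np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)

    def test_against_brute_force_simulation(self, pop_model):
        """Monte-Carlo oracle: the implied covariance must match the
        sample covariance of a large simulated draw within 3 MC
        standard errors elementwise."""
        n = 1_000_000
        _, moments = cs.simulate_sample(pop_model, n, seed=123)
        sigma = pop_model.sigma
        d = np.diag(sigma)
        # var of a sample covariance under normality
        mc_se = np.sqrt((np.outer(d, d) + sigma ** 2) / n)
        assert np.all(np.abs(moments.S - sigma) < 3.5 * mc_se)

    @pytest.mark.parametrize("variant", ["unit", "free", "relaxed"])
    def test_block_component_submatrix_reproduced_at_optimum(
        self, spec, moments180, variant
    ):
        """Each block's component covariance submatrix is perfectly
        replicated by every H-O variant."""
        table = cs.build_ho_specification(spec, variant, moments=moments180)
        fit = cs.fit_ml(table, moments180, seed=0)
        S = fit.moments.S
        names = list(fit.moments.names)
        for block in table.blocks:
            idx = [names.index(c) for c in block.components]
            np.testing.assert_allclose(
                fit.sigma[np.ix_(idx, idx)], S[np.ix_(idx, idx)], atol=1e-6
            )

    def test_implied_composite_excrescent_covariance_is_zero(self, pop_model):
        compiled = pop_model.compiled
        full = compiled.full_sigma(pop_model.theta)
        for block in pop_model.table.blocks:
            i = compiled.index[block.name]
            for nu in block.composites[1:]:
                assert full[i, compiled.index[nu]] == pytest.approx(0.0, abs=1e-12)


class TestGradients:
    def test_analytic_discrepancy_gradient_matches_finite_differences(
        self, spec, moments180
    ):
        table = cs.build_ho_specification(spec, "relaxed", moments=moments180)
        compiled = CompiledTable(table)
        rng = np.random.default_rng(2)
        S = moments180.reorder(table.observed).S
        theta = _random_admissible(compiled, rng)
        f0, grad = compiled.discrepancy(theta, S)
        assert np.isfinite(f0)
        num = np.empty_like(grad)
        for k in range(compiled.q):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            num[k] = (
                compiled.discrepancy(tp, S)[0] - compiled.discrepancy(tm, S)[0]
            ) / (2 * h)
        np.testing.assert_allclose(grad, num, atol=1e-6, rtol=1e-5)

    def test_analytic_dsigma_matches_finite_differences(self, spec, moments180):
        table = cs.build_ho_specification(spec, "free", moments=moments180)
        compiled = CompiledTable(table)
        theta = _random_admissible(compiled, np.random.default_rng(3))
        D = compiled.dsigma(theta)
        for k in range(compiled.q):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            num = (compiled.sigma(tp) - compiled.sigma(tm)) / (2 * h)
            np.testing.assert_allclose(D[k], num, atol=1e-6)


class TestTwoStepReduce:
    def test_unit_weight_composite_variance(self):
        # 2 components, variances 1, covariance 0.5 -> composite variance 3
        moments = cs.SampleMoments(
            ("x1", "x2"), np.array([[1.0, 0.5], [0.5, 1.0]]), 100
        )
        blocks = (cs.CompositeBlock("C", ("x1", "x2")),)
        reduced = cs.two_step_reduce(moments, blocks)
        assert reduced.S[0, 0] == pytest.approx(3.0)
        assert reduced.names == ("C",)

    def test_passthrough_rows_unchanged(self, pop_model):
        moments = pop_model.population_moments(180)
        reduced = cs.two_step_reduce(moments, pop_model.spec.blocks)
        assert reduced.names == ("Soil", "Land", "cover", "colf")
        i, j = reduced.names.index("cover"), reduced.names.index("colf")
        oi = moments.names.index("cover")
        oj = moments.names.index("colf")
        assert reduced.S[i, j] == pytest.approx(moments.S[oi, oj])
        assert reduced.S[i, i] == pytest.approx(moments.S[oi, oi])
        assert reduced.n == moments.n

    def test_unknown_weight_variable_rejected(self):
        moments = cs.SampleMoments(("x1", "x2"), np.eye(2), 50)
        blocks = (cs.CompositeBlock("C", ("x1", "ghost")),)
        with pytest.raises(cs.exceptions.InputError, match="ghost"):
            cs.two_step_reduce(moments, blocks)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        X1 = rng.normal(size=(8, 3))
        X2 = rng.normal(size=(8, 3))
        S1, S2 = X1.T @ X1, X2.T @ X2
        names = ("x1", "x2", "p")
        blocks = (cs.CompositeBlock("C", ("x1", "x2")),)

        def red(S):
            return cs.two_step_reduce(
                cs.SampleMoments(names, (S + S.T) / 2, 10), blocks
            ).S

        combo = a * S1 + b * S2
        np.testing.assert_allclose(
            red(combo), a * red(S1) + b * red(S2), atol=1e-10
        )


class TestLocalIdentification:
    def test_free_table_has_full_rank(self, spec):
        table = cs.build_ho_specification(spec, "free", indicator_variances=IV)
        report = cs.check_local_identification(table, seed=0)
        assert report.rank == report.q == 20
        assert not report.deficient

    def test_rule5_violation_is_rank_deficient(self, spec):
        isolated = dataclasses.replace(
            spec, paths=(("Comp", "Colo"),), exo_covariances=()
        )
        table = cs.build_ho_specification(
            isolated, "free", indicator_variances=IV, enforce_connectivity=False
        )
        report = cs.check_local_identification(table, seed=0)
        assert report.deficient
        assert report.rank < report.q
        assert len(report.null_space_labels) > 0

    def test_all_fixed_table_rank_zero(self):
        table = ParameterTable(
            variables=("a",),
            observed=("a",),
            rows=[ParamRow("a", "a", "variance", "fixed", value=1.0)],
        )
        report = cs.check_local_identification(table, seed=0)
        assert report.rank == report.q == 0
        assert not report.deficient

    def test_finite_difference_jacobian_agrees_with_analytic(self, spec):
        """Dual route: the numeric Jacobian used by the diagnostic must
        match the engine's analytic derivative."""
        table = cs.build_ho_specification(spec, "free", indicator_variances=IV)
        compiled = CompiledTable(table)
        theta = _random_admissible(compiled, np.random.default_rng(0))
        D = compiled.dsigma(theta)
        iu = np.triu_indices(compiled.p)
        for k in range(compiled.q):
            h = 1e-6 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            num = (compiled.sigma(tp)[iu] - compiled.sigma(tm)[iu]) / (2 * h)
            np.testing.assert_allclose(D[k][iu], num, atol=1e-6)
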