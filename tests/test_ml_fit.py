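"""Maximum-likelihood estimation: self-consistency, weight recovery,
standardization, equivalences between specifications, standard errors."""
import dataclasses

import numpy as np
import pytest

import compositesem as cs
from compositesem.fit import _loading_matrix, delta_method_se
from compositesem.model import CompositeBlock, Latent, ModelSpec
from compositesem.table import ParamRow, ParameterTable

from conftest import std_map

IV = {"cover": 1.0, "colf": 1.0}


def saturated_table(names):
    rows = [
        ParamRow(v, v, "variance", "free", label=f"v_{v}") for v in names
    ]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append(ParamRow(a, b, "covariance", "free", label=f"c_{a}_{b}"))
    return ParameterTable(variables=tuple(names), observed=tuple(names), rows=rows)


class TestFitML:
    def test_saturated_model_reproduces_sample_exactly(self, moments180):
        table = saturated_table(list(moments180.names))
        fit = cs.fit_ml(table, moments180, seed=0)
        assert fit.converged
        assert fit.f_min == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.sigma, moments180.as_ml().S, atol=1e-6)

    def test_population_self_fit_recovers_truth(self, pop_model, pop_moments):
        table = cs.build_ho_specification(
            pop_model.spec, "free", moments=pop_moments
        )
        fit = cs.fit_ml(table, pop_moments, seed=1)
        assert fit.converged
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        for label, truth in pop_model.true_values.items():
            assert fit.estimates[label] == pytest.approx(truth, abs=1e-4), label

    def test_nonconvergence_flag_instead_of_exception(self, spec, moments180):
        table = cs.build_ho_specification(spec, "free", moments=moments180)
        with pytest.warns(cs.exceptions.ConvergenceWarning):
            fit = cs.fit_ml(table, moments180, seed=0, maxiter=2, max_retries=0)
        assert not fit.converged

    def test_non_positive_definite_moments_rejected(self, spec):
        S = np.ones((7, 7))
        moments = cs.SampleMoments(spec.observed_names, S, 100)
        table = cs.build_ho_specification(spec, "free", indicator_variances=IV)
        with pytest.raises(cs.exceptions.InputError, match="positive definite"):
            cs.fit_ml(table, moments)

    def test_unbiased_divisor_rescaled_before_fitting(self, spec, moments180):
        """An unbiased (n-1 divisor) matrix must give the same fit as its
        ML-rescaled counterpart."""
        n = moments180.n
        unb = cs.SampleMoments(
            moments180.names, moments180.S * n / (n - 1), n, "unbiased"
        )
        t = cs.build_ho_specification(spec, "free", moments=moments180)
        f_ml = cs.fit_ml(t, moments180, seed=0)
        f_unb = cs.fit_ml(t, unb, seed=0)
        assert f_unb.f_min == pytest.approx(f_ml.f_min, abs=1e-10)


class TestRecoverWeights:
    def test_unit_variant_weights_are_one(self, fits180):
        fit = fits180["unit"].result_
        for block in ("Soil", "Land"):
            w = cs.recover_weights(fit, block)
            np.testing.assert_allclose(w.to_numpy(), 1.0, atol=1e-8)

    def test_weight_times_loading_matrix_is_first_unit_vector(self, fits180):
        fit = fits180["free"].result_
        for binfo in fit.table.blocks:
            lam = _loading_matrix(fit.compiled, fit.theta, binfo)
            w = cs.recover_weights(fit, binfo.name).to_numpy()
            e1 = np.zeros(len(binfo.components))
            e1[0] = 1.0
            np.testing.assert_allclose(w @ lam, e1, atol=1e-10)

    def test_full_inverse_identity_on_four_component_block(self):
        """W' Lambda = I within 1e-10 for a k = 4 block."""
        spec4 = ModelSpec(
            observed_names=("x1", "x2", "x3", "x4", "y"),
            blocks=(CompositeBlock("C", ("x1", "x2", "x3", "x4")),),
            paths=(("C", "y"),),
        )
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 4))
        y = X @ np.array([0.5, 0.3, -0.2, 0.4]) + rng.normal(
            scale=0.8, size=400
        )
        data = np.column_stack([X, y])
        moments = cs.moments_from_data(
            __import__("pandas").DataFrame(
                data, columns=["x1", "x2", "x3", "x4", "y"]
            )
        )
        table = cs.build_ho_specification(spec4, "free", moments=moments)
        fit = cs.fit_ml(table, moments, seed=0)
        assert fit.converged
        binfo = fit.table.blocks[0]
        lam = _loading_matrix(fit.compiled, fit.theta, binfo)
        W_t = np.linalg.inv(lam)
        np.testing.assert_allclose(W_t @ lam, np.eye(4), atol=1e-10)

    def test_free_weights_recovered_up_to_sum_normalization(
        self, pop_model, pop_moments
    ):
        table = cs.build_ho_specification(pop_model.spec, "free", moments=pop_moments)
        fit = cs.fit_ml(table, pop_moments, seed=1)
        for block in ("Soil", "Land"):
            w = cs.recover_weights(fit, block).to_numpy()
            truth = pop_model.true_weights(block).to_numpy()
            np.testing.assert_allclose(
                w / w.sum(), truth / truth.sum(), atol=1e-4
            )


class TestStandardization:
    def test_standardized_weights_match_direct_formula(self, fits180):
        fit = fits180["free"].result_
        for binfo in fit.table.blocks:
            w = cs.recover_weights(fit, binfo.name).to_numpy()
            full = fit.sigma_full
            idx = fit.compiled.index
            sd = np.sqrt(np.diag(full))
            expected = w * np.array(
                [sd[idx[c]] for c in binfo.components]
            ) / sd[idx[binfo.name]]
            got = cs.standardized_weights(fit, binfo.name).to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_population_fit_standardized_paths_equal_truth(
        self, pop_model, pop_moments
    ):
        table = cs.build_ho_specification(pop_model.spec, "free", moments=pop_moments)
        fit = cs.fit_ml(table, pop_moments, seed=1)
        got = std_map(fit)
        truth = {
            (r.source, r.target, r.role): r.std
            for r in pop_model.true_standardized().itertuples()
        }
        for key, val in truth.items():
            assert got[key] == pytest.approx(val, abs=1e-4), key

    def test_standardized_covariances_are_correlations(self, fits180):
        sol = fits180["relaxed"].standardized_solution_(with_se=False)
        covs = sol[sol.role == "covariance"]["std"]
        assert ((covs >= -1) & (covs <= 1)).all()


class TestEquivalences:
    def test_two_step_equals_unit_weight_ho(self, fits180):
        su = std_map(fits180["unit"])
        st_ = std_map(fits180["two_step"])
        for key, val in st_.items():
            assert su[key] == pytest.approx(val, abs=1e-4), key

    def test_one_step_equals_relaxed_ho(self, fits180):
        rel, one = fits180["relaxed"], fits180["one_step"]
        assert one.chi2_ == pytest.approx(rel.chi2_, abs=1e-6)
        assert one.dof_ == rel.dof_
        sr, so = std_map(rel), std_map(one)
        for key, val in so.items():
            if key[2] != "path":
                continue  # the one-step model has no Soil-Land covariance
            assert sr[key] == pytest.approx(val, abs=1e-6), key

    def test_nested_chi_square_monotonicity(self, fits180):
        assert (
            fits180["unit"].chi2_
            >= fits180["free"].chi2_
            >= fits180["relaxed"].chi2_
        )


class TestInvariances:
    def test_shared_and_reference_respecification(self, spec, moments180):
        base = cs.fit_ml(
            cs.build_ho_specification(spec, "free", moments=moments180),
            moments180, seed=5,
        )
        alt_spec = dataclasses.replace(
            spec,
            blocks=(
                CompositeBlock(
                    "Soil", ("text", "mois", "pH"),
                    shared_component="mois", references=("pH", "text"),
                ),
                CompositeBlock(
                    "Land", ("age", "dist"),
                    shared_component="dist", references=("age",),
                ),
            ),
        )
        alt = cs.fit_ml(
            cs.build_ho_specification(alt_spec, "free", moments=moments180),
            moments180, seed=5,
        )
        assert alt.f_min == pytest.approx(base.f_min, abs=1e-9)
        assert alt.dof == base.dof
        sb, sa = std_map(base), std_map(alt)
        for key in sb:
            assert sa[key] == pytest.approx(sb[key], abs=1e-6), key
        for block in ("Soil", "Land"):
            np.testing.assert_allclose(
                cs.recover_weights(alt, block).to_numpy(),
                cs.recover_weights(base, block).to_numpy(),
                atol=1e-6,
            )

    @pytest.mark.parametrize("scale", ["reference", "variance_std"])
    def test_scale_method_respecification(self, spec, moments180, scale):
        base = cs.fit_ml(
            cs.build_ho_specification(spec, "free", moments=moments180),
            moments180, seed=5,
        )
        alt = cs.fit_ml(
            cs.build_ho_specification(
                spec, "free", moments=moments180, scale_method=scale
            ),
            moments180, seed=5,
        )
        assert alt.f_min == pytest.approx(base.f_min, abs=1e-9)
        assert alt.dof == base.dof
        sb, sa = std_map(base), std_map(alt)
        for key in sb:
            assert sa[key] == pytest.approx(sb[key], abs=1e-6), key
        # weights agree up to an overall block scale
        for block in ("Soil", "Land"):
            wb = cs.recover_weights(base, block).to_numpy()
            wa = cs.recover_weights(alt, block).to_numpy()
            np.testing.assert_allclose(wa / wa.sum(), wb / wb.sum(), atol=1e-6)


class TestStandardErrors:
    def test_all_standard_errors_positive(self, fits180):
        fit = fits180["free"].result_
        ses = cs.standard_errors(fit)
        assert all(se > 0 for se in ses.values())

    @staticmethod
    def _bootstrap_weights(pop_model, n, reps, entropy):
        out = []
        for child in np.random.SeedSequence(entropy).spawn(reps):
            _, mom = cs.simulate_sample(
                pop_model, n, np.random.default_rng(child)
            )
            t = cs.build_ho_specification(pop_model.spec, "free", moments=mom)
            f = cs.fit_ml(t, mom, seed=int(child.generate_state(1)[0] % 2**31))
            if f.converged:
                out.append(cs.recover_weights(f, "Soil").to_numpy())
        return np.array(out)

    @staticmethod
    def _delta_se_at_truth(pop_model, n):
        pop_moments = pop_model.population_moments(n)
        table = cs.build_ho_specification(
            pop_model.spec, "free", moments=pop_moments
        )
        fit = cs.fit_ml(table, pop_moments, seed=1)
        return cs.weights_se(fit, "Soil").to_numpy()

    def test_delta_method_against_parametric_bootstrap(self, pop_model):
        """Delta-method SEs of the recovered soil weights vs the
        Monte-Carlo spread over 500 parametric replicates of n = 500."""
        delta = self._delta_se_at_truth(pop_model, 500)
        boot = self._bootstrap_weights(pop_model, 500, 500, 2024)
        np.testing.assert_allclose(delta, boot.std(axis=0, ddof=1), rtol=0.15)

    def test_delta_method_matches_bootstrap_bulk_spread_at_n_180(self, pop_model):
        """At n = 180 the recovered-weight sampling distribution is
        heavy-tailed (weights are elements of an inverted matrix), so the
        asymptotic SE is compared to the robust interquartile spread."""
        delta = self._delta_se_at_truth(pop_model, 180)
        boot = self._bootstrap_weights(pop_model, 180, 500, 2024)
        robust = (
            np.percentile(boot, 75, axis=0) - np.percentile(boot, 25, axis=0)
        ) / 1.349
        np.testing.assert_allclose(delta, robust, rtol=0.15)
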