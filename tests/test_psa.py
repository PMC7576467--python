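import numpy as np
import pytest
from scipy import stats

from medlysim import (beta_from_point_range, build_default_specs, ceac,
                      dirichlet_row, fit_negbin_mle, gamma_from_moments,
                      lognormal_from_ci, run_psa, sample_parameters,
                      simulate_cohort)
from medlysim.economics import compute_icer
from medlysim.psa import DistributionSpec, PsaIteration


class TestGamma:
    def test_mean_equal_sd_is_exponential(self):
        spec = gamma_from_moments(5.0, 5.0)
        assert spec.parameters["shape"] == pytest.approx(1.0)

    def test_hospitalization_cost_moments(self):
        spec = gamma_from_moments(8908.0, 16867.0)
        assert spec.parameters["shape"] == pytest.approx(0.2789, abs=5e-4)
        assert spec.parameters["scale"] == pytest.approx(31937, rel=5e-4)

    def test_moment_recovery(self, rng):
        spec = gamma_from_moments(8908.0, 16867.0)
        x = spec.sample(rng, 100_000)
        assert abs(x.mean() - 8908.0) / 8908.0 < 0.01

    def test_invalid_moments(self):
        with pytest.raises(ValueError):
            gamma_from_moments(-1.0, 2.0)
        with pytest.raises(ValueError):
            gamma_from_moments(1.0, 0.0)


class TestLognormal:
    def test_mortality_rr_parameters(self):
        spec = lognormal_from_ci(0.81, 0.70, 0.94)
        assert spec.parameters["mu"] == pytest.approx(-0.21072, abs=1e-5)
        assert spec.parameters["sigma"] == pytest.approx(0.07520, abs=1e-5)

    def test_ci_round_trip(self):
        spec = lognormal_from_ci(0.81, 0.70, 0.94)
        mu, sigma = spec.parameters["mu"], spec.parameters["sigma"]
        lo = np.exp(mu - 1.959964 * sigma)
        hi = np.exp(mu + 1.959964 * sigma)
        # the point sits at the geometric midpoint; printed bounds are
        # recovered within their own rounding
        assert lo == pytest.approx(0.70, abs=0.03)
        assert hi == pytest.approx(0.94, abs=0.03)

    def test_degenerate_interval(self):
        spec = lognormal_from_ci(0.5, 0.5, 0.5)
        assert spec.parameters["sigma"] == 0.0

    def test_order_violation(self):
        with pytest.raises(ValueError):
            lognormal_from_ci(0.5, 0.6, 0.7)


class TestBeta:
    def test_symmetric_range(self):
        spec = beta_from_point_range(0.5, 0.4, 0.6)
        sd = (0.6 - 0.4) / (2 * 1.959964)
        assert sd == pytest.approx(0.05102, abs=1e-5)
        assert spec.parameters["alpha"] == pytest.approx(47.52, abs=0.05)
        assert spec.parameters["alpha"] == pytest.approx(
            spec.parameters["beta"])

    def test_zero_width_becomes_fixed(self):
        spec = beta_from_point_range(0.3, 0.3, 0.3)
        assert spec.family == "fixed"
        assert spec.parameters["value"] == 0.3

    def test_moment_recovery(self, rng):
        spec = beta_from_point_range(0.81, 0.81, 0.90)
        x = spec.sample(rng, 100_000)
        assert abs(x.mean() - 0.81) < 0.005

    def test_point_outside_unit_interval(self):
        with pytest.raises(ValueError):
            beta_from_point_range(1.2, 0.9, 1.0)

    def test_inverted_range_swapped(self):
        spec = beta_from_point_range(0.5, 0.6, 0.4)
        assert spec.family == "beta"


class TestDirichlet:
    ROW = [0.977, 0.019, 0.004, 0.0]

    def test_samples_on_simplex(self, rng):
        spec = dirichlet_row(self.ROW, 500.0)
        x = spec.sample(rng, 1000)
        np.testing.assert_allclose(x.sum(axis=1), 1.0, atol=1e-12)

    def test_concentration_limit(self, rng):
        spec = dirichlet_row(self.ROW, 1e6)
        x = spec.sample(rng, 2000)
        assert np.max(np.abs(x.mean(axis=0) - np.array(self.ROW))) < 0.01

    def test_mean_recovery(self, rng):
        spec = dirichlet_row(self.ROW, 500.0)
        x = spec.sample(rng, 100_000)
        np.testing.assert_allclose(x.mean(axis=0), self.ROW, atol=0.005)

    def test_invalid_row(self):
        with pytest.raises(ValueError):
            dirichlet_row([0.5, 0.2, 0.2, 0.2], 500.0)
        with pytest.raises(ValueError):
            dirichlet_row(self.ROW, 0.0)


class TestNegbinMle:
    def test_parameter_recovery(self, rng):
        x = rng.negative_binomial(1, 1 / (1 + 2), size=5000)  # mean 2, size 1
        spec = fit_negbin_mle(x)
        assert abs(spec.parameters["mean"] - 2.0) < 0.1
        assert abs(spec.parameters["size"] - 1.0) < 0.2
        assert spec.parameters["mean"] == pytest.approx(x.mean(), abs=1e-6)

    def test_equidispersed_falls_back_to_poisson(self):
        with pytest.warns(UserWarning, match="Poisson"):
            spec = fit_negbin_mle([3, 3, 3, 3])
        assert spec.parameters["size"] == np.inf

    def test_beats_poisson_on_overdispersed_counts(self, rng):
        x = rng.negative_binomial(0.8, 0.3, size=2000)
        spec = fit_negbin_mle(x)
        pois_ll = float(np.sum(stats.poisson.logpmf(x, x.mean())))
        assert spec.parameters["loglik"] >= pois_ll

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_negbin_mle([2])
        with pytest.raises(ValueError):
            fit_negbin_mle([0, 0, 0])


class TestSampleParameters:
    def test_all_fixed_specs_identity(self, params, rng):
        specs = {"hosp_cost_mean": DistributionSpec(
            family="fixed", parameters={"value": params.hosp_cost_mean})}
        out = sample_parameters(params, specs, rng)
        assert out.to_dict() == params.to_dict()

    def test_seeded_reproducibility(self, params):
        specs = build_default_specs(params)
        a = sample_parameters(params, specs, np.random.default_rng(3))
        b = sample_parameters(params, specs, np.random.default_rng(3))
        assert a.to_dict() == b.to_dict()

    def test_sampled_sets_remain_valid(self, params):
        from medlysim import validate

        specs = build_default_specs(params)
        rng = np.random.default_rng(5)
        for _ in range(50):
            assert validate(sample_parameters(params, specs, rng)) == []

    def test_hospital_cost_moment_recovery(self, params):
        specs = build_default_specs(params)
        rng = np.random.default_rng(17)
        draws = [sample_parameters(params, specs, rng).hosp_cost_mean
                 for _ in range(1000)]
        assert abs(np.mean(draws) - 8908.0) / 8908.0 < 0.05

    def test_unknown_spec_rejected(self, params, rng):
        with pytest.raises(KeyError):
            sample_parameters(params, {"no_such_field": DistributionSpec(
                family="fixed", parameters={"value": 1.0})}, rng)


class TestRunPsa:
    def test_degenerate_psa_equals_deterministic(self, short_params,
                                                 small_cohort):
        """With every spec fixed, one PSA iteration reproduces the
        deterministic run exactly (the module's oracle)."""
        fixed = {"hosp_cost_mean": DistributionSpec(
            family="fixed",
            parameters={"value": short_params.hosp_cost_mean})}
        det = compute_icer(simulate_cohort(small_cohort, short_params,
                                           seed=6))
        res = run_psa(small_cohort, short_params, n_iterations=1, seed=6,
                      specs=fixed)
        assert res.iterations[0].delta_cost == pytest.approx(det.delta_cost,
                                                             abs=1e-8)
        assert res.iterations[0].delta_qaly == pytest.approx(det.delta_qaly,
                                                             abs=1e-10)

    def test_output_length_and_quadrants(self, short_params, small_cohort):
        res = run_psa(small_cohort, short_params, n_iterations=20, seed=6)
        assert len(res) == 20
        assert sum(res.quadrant_proportions().values()) == pytest.approx(1.0)

    def test_reproducible(self, short_params, small_cohort):
        a = run_psa(small_cohort, short_params, n_iterations=5, seed=9)
        b = run_psa(small_cohort, short_params, n_iterations=5, seed=9)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)


class TestCeac:
    def test_single_iteration_steps_at_its_icer(self):
        its = [PsaIteration(0, delta_cost=5011.0, delta_qaly=0.566)]
        icer = 5011.0 / 0.566
        curve = ceac(its, [0.0, icer - 100, icer + 100, 1e6])
        assert list(curve["probability"]) == [0.0, 0.0, 1.0, 1.0]

    def test_zero_wtp_counts_cost_savers(self):
        its = [PsaIteration(0, -5.0, 0.1), PsaIteration(1, 5.0, 0.1)]
        curve = ceac(its, [0.0])
        assert curve["probability"].iloc[0] == 0.5

    def test_nondecreasing_when_all_gain_qalys(self, rng):
        its = [PsaIteration(i, rng.normal(5000, 3000),
                            abs(rng.normal(0.5, 0.2)) + 1e-3)
               for i in range(200)]
        curve = ceac(its, np.arange(0, 100_001, 5000))
        assert np.all(np.diff(curve["probability"]) >= 0)
        assert curve["probability"].between(0, 1).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            ceac([], [0.0])
        with pytest.raises(ValueError):
            ceac([PsaIteration(0, 1.0, 1.0)], [-5.0])
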