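import numpy as np
import pytest

from medlysim import HealthState, SimState, discount_factor, generate_cohort
from medlysim.engine import (cohort_draws, simulate_cohort, simulate_patient,
                             step_patient)


class TestDiscounting:
    def test_month_zero(self):
        assert discount_factor(0, 0.015) == 1.0

    def test_zero_rate(self):
        assert discount_factor(240, 0.0) == 1.0

    def test_one_year_at_reference_rate(self):
        assert discount_factor(12, 0.015) == pytest.approx(1 / 1.015)
        assert discount_factor(12, 0.015) == pytest.approx(0.985222,
                                                           abs=5e-7)

    def test_validation(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.015)
        with pytest.raises(ValueError):
            discount_factor(1, -0.1)


def community_state(klass=1, age=60.0):
    return SimState(current=HealthState(klass), resident_nyha=klass,
                    current_age=age)


class TestStepPatient:
    def test_dead_patients_are_never_stepped(self, short_params,
                                             small_cohort):
        state = community_state()
        state.alive = False
        state.current = HealthState.DEAD
        with pytest.raises(ValueError):
            step_patient(state, small_cohort[0], short_params, "standard",
                         [0.5, 0.5, 0.5])

    def test_forced_death_absorbs(self, short_params, small_cohort):
        # an overwhelming hazard makes the monthly death probability ~1
        state = community_state()
        nxt, cost, util = step_patient(state, small_cohort[0], short_params,
                                       "standard", [0.999, 0.5, 0.5],
                                       hazard_annual=1e9)
        assert nxt.current is HealthState.DEAD
        assert not nxt.alive
        assert cost == 0.0 and util == 0.0

    def test_transition_by_cumulative_row(self, short_params, small_cohort):
        """Draw 0.98 against the class-I row (0.977, 0.019, 0.004, 0)
        cumulated in column order lands in class II."""
        state = community_state(klass=1)
        nxt, _, _ = step_patient(state, small_cohort[0], short_params,
                                 "standard", [1.0, 1.0, 0.98],
                                 hazard_annual=0.0)
        assert nxt.current is HealthState.NYHA2
        assert nxt.resident_nyha == 2

    def test_admission_enters_index_then_readmit(self, short_params,
                                                 small_cohort):
        p = short_params.copy()
        p.hosp_prob_monthly = [1.0, 1.0, 1.0, 1.0]
        state = community_state(klass=2)
        nxt, cost, util = step_patient(state, small_cohort[0], p, "standard",
                                       [1.0, 0.0, 0.5], hazard_annual=0.0)
        assert nxt.current is HealthState.HOSP_INDEX
        assert cost == pytest.approx(p.hosp_cost_mean)
        assert util == pytest.approx(p.utilities_by_class[1]
                                     - p.hosp_disutility)
        # surviving hospitalization and drawing another admission gives the
        # readmission state (persistent scope allows hospital chains)
        nxt2, _, _ = step_patient(nxt, small_cohort[0], p, "standard",
                                  [1.0, 0.0, 0.5], hazard_annual=0.0)
        assert nxt2.current is HealthState.HOSP_READMIT

    def test_discharge_returns_to_resident_class(self, short_params,
                                                 small_cohort):
        p = short_params.copy()
        state = SimState(current=HealthState.HOSP_INDEX, resident_nyha=3,
                         current_age=60.0, ever_hospitalized=True)
        nxt, _, _ = step_patient(state, small_cohort[0], p, "standard",
                                 [1.0, 1.0, 1.0], hazard_annual=0.0)
        assert nxt.current is HealthState.NYHA3


class TestSimulatePatient:
    def test_quiet_year_accrues_exact_utility(self, params, small_cohort):
        """With no deaths, hospitalizations or discounting, 12 months in
        class I accrue exactly the class utility as QALYs."""
        p = params.copy()
        p.horizon_months = 12
        p.discount_rate_annual = 0.0
        p.hosp_prob_monthly = [0.0, 0.0, 0.0, 0.0]
        p.readmit_prob_30d = 0.0
        p.nyha_transition_matrix = np.eye(4).tolist()
        p.shfm["baseline_annual_hazard"] = 1e-12
        profile = small_cohort[0]
        profile.nyha_class = 1
        res = simulate_patient(profile, p, "standard", seed=0)
        assert res.discounted_qaly == pytest.approx(0.81, abs=1e-12)
        assert res.life_months == 12
        assert res.admissions == 0

    def test_seed_determinism(self, short_params, small_cohort):
        a = simulate_patient(small_cohort[1], short_params, "medly", seed=5)
        b = simulate_patient(small_cohort[1], short_params, "medly", seed=5)
        assert a == b

    def test_discounted_below_undiscounted(self, short_params, small_cohort):
        p0 = short_params.copy()
        p0.discount_rate_annual = 0.0
        draws = cohort_draws(1, short_params.horizon_months, 3)[0]
        disc = simulate_patient(small_cohort[2], short_params, "standard",
                                draws=draws)
        undisc = simulate_patient(small_cohort[2], p0, "standard",
                                  draws=draws)
        assert disc.discounted_cost <= undisc.discounted_cost
        assert disc.discounted_qaly <= undisc.discounted_qaly

    def test_qaly_bounded_by_horizon(self, short_params, small_cohort):
        res = simulate_patient(small_cohort[3], short_params, "standard",
                               seed=9)
        max_q = short_params.horizon_months / 12 * max(
            short_params.utilities_by_class)
        assert 0.0 <= res.discounted_qaly <= max_q


class TestSimulateCohort:
    def test_empty_cohort_rejected(self, short_params, params):
        empty = generate_cohort(0, params=params, seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(empty, short_params, seed=0)

    def test_determinism(self, short_params, small_cohort):
        a = simulate_cohort(small_cohort, short_params, seed=2)
        b = simulate_cohort(small_cohort, short_params, seed=2)
        for arm in ("standard", "medly"):
            np.testing.assert_array_equal(a.cost[arm], b.cost[arm])
            np.testing.assert_array_equal(a.qaly[arm], b.qaly[arm])

    def test_null_intervention_equivalence(self, null_intervention,
                                           small_cohort):
        """With unit relative risks and zero program costs, common random
        numbers make the two arms identical patient by patient."""
        res = simulate_cohort(small_cohort, null_intervention, seed=2)
        np.testing.assert_allclose(res.cost["medly"], res.cost["standard"])
        np.testing.assert_allclose(res.qaly["medly"], res.qaly["standard"])
        np.testing.assert_array_equal(res.admissions["medly"],
                                      res.admissions["standard"])

    @pytest.mark.parametrize("scope", ["persistent", "first_cycle"])
    def test_vectorized_matches_reference_implementation(self, short_params,
                                                         small_cohort,
                                                         scope):
        """The vectorized cohort engine and the per-patient reference
        implementation produce identical trajectories."""
        p = short_params.copy()
        p.readmission_scope = scope
        draws = cohort_draws(len(small_cohort), p.horizon_months, 7)
        vec = simulate_cohort(small_cohort, p, seed=7, draws=draws)
        for arm in ("standard", "medly"):
            for i in range(len(small_cohort)):
                ref = simulate_patient(small_cohort[i], p, arm,
                                       draws=draws[i])
                got = vec.arm_result(i, arm)
                assert got.discounted_cost == pytest.approx(
                    ref.discounted_cost, abs=1e-8), (arm, i)
                assert got.discounted_qaly == pytest.approx(
                    ref.discounted_qaly, abs=1e-10), (arm, i)
                assert got.life_months == ref.life_months, (arm, i)
                assert got.admissions == ref.admissions, (arm, i)

    def test_admissions_increase_with_readmission_probability(
            self, short_params, small_cohort):
        lo = short_params.replace(readmit_prob_30d=0.05)
        hi = short_params.replace(readmit_prob_30d=0.40)
        draws = cohort_draws(len(small_cohort), short_params.horizon_months,
                             4)
        a = simulate_cohort(small_cohort, lo, seed=4, draws=draws)
        b = simulate_cohort(small_cohort, hi, seed=4, draws=draws)
        assert b.admissions["standard"].mean() > \
            a.admissions["standard"].mean()

    def test_identity_transitions_conserve_class_occupancy(self, params,
                                                           small_cohort):
        p = params.copy()
        p.horizon_months = 24
        p.nyha_transition_matrix = np.eye(4).tolist()
        p.hosp_prob_monthly = [0.0] * 4
        p.readmit_prob_30d = 0.0
        p.shfm["baseline_annual_hazard"] = 1e-12
        res = simulate_cohort(small_cohort, p, seed=1)
        # nobody dies or moves: every patient accrues their own class
        # utility for the full horizon
        util = np.asarray(p.utilities_by_class)[
            small_cohort.data["nyha_class"].to_numpy() - 1]
        df = np.sum([(1.015) ** (-t / 12) for t in range(24)])
        np.testing.assert_allclose(res.qaly["standard"], util / 12 * df,
                                   rtol=1e-10)

    def test_mcse_convention(self, short_params, small_cohort):
        res = simulate_cohort(small_cohort, short_params, seed=2)
        mcse = res.mcse("cost")["standard"]
        expected = np.std(res.cost["standard"], ddof=1) / np.sqrt(
            len(small_cohort))
        assert mcse == pytest.approx(expected)
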