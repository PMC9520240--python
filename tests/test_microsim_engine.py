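"""Engine tests: state machine, intervention logic, arm aggregation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from t2dsim.economics import DiscountSpec, aggregate_trajectory
from t2dsim.microsim_engine import (
    HealthState,
    InterventionPolicy,
    InterventionStatus,
    ModelSet,
    ParameterSet,
    Strategy,
    assign_intervention,
    assign_interventions,
    classify_risk,
    draw_streams,
    effective_t2d_prob,
    reclassification_rate,
    run_arm,
    run_pair,
    simulate_individual,
    step,
)
from t2dsim.survival_models import apply_hazard_ratio


class TestClassifyRisk:
    def test_band_edges(self):
        assert classify_risk(0.15) == "high"
        assert classify_risk(0.20) == "very_high"
        assert classify_risk(0.05) == "moderate"
        assert classify_risk(0.01) == "very_low"

    def test_sub_high_categories_never_trigger(self, policy):
        for risk in (0.0, 0.05, 0.15, 0.199):
            assert risk < policy.risk_threshold

    def test_invalid_risk_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(1.5)


class TestAssignIntervention:
    def row(self, no_prs, with_prs):
        return pd.Series({"risk10_no_prs": no_prs, "risk10_with_prs": with_prs})

    def test_prs_arm_high_risk_with_uptake_gets_both(self, policy):
        got = assign_intervention(self.row(0.15, 0.25), Strategy.PRS, policy, 0.1)
        assert got == InterventionStatus.LIFESTYLE_MEDICAL

    def test_prs_arm_high_risk_without_uptake_gets_lifestyle(self, policy):
        got = assign_intervention(self.row(0.15, 0.25), Strategy.PRS, policy, 0.9)
        assert got == InterventionStatus.LIFESTYLE

    def test_prs_arm_below_threshold_gets_none(self, policy):
        got = assign_intervention(self.row(0.15, 0.18), Strategy.PRS, policy, 0.0)
        assert got == InterventionStatus.NONE

    def test_usual_arm_band_member_gets_none(self, policy):
        got = assign_intervention(self.row(0.15, 0.25), Strategy.USUAL, policy, 0.0)
        assert got == InterventionStatus.NONE

    def test_missing_risk_column_is_an_error(self, policy):
        cohort = pd.DataFrame({"risk10_no_prs": [0.15]})
        with pytest.raises(ValueError, match="risk10_with_prs"):
            assign_interventions(cohort, Strategy.PRS, policy, np.array([0.5]))

    def test_uptake_fraction_matches_policy(self, policy):
        n = 10_000
        cohort = pd.DataFrame(
            {"risk10_no_prs": np.full(n, 0.15), "risk10_with_prs": np.full(n, 0.25)}
        )
        u = np.random.default_rng(3).random(n)
        status = assign_interventions(cohort, Strategy.PRS, policy, u)
        frac_medical = (status == InterventionStatus.LIFESTYLE_MEDICAL).mean()
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac_medical - policy.medical_uptake) < 3 * se


class TestEffectiveT2dProb:
    def test_none_status_passes_through(self, policy):
        assert effective_t2d_prob(0.08, 0, 3, policy) == 0.08

    def test_lifestyle_applies_hr(self, policy):
        base = 1.0 - np.exp(-0.1)
        got = effective_t2d_prob(base, 1, 3, policy)
        assert got == pytest.approx(1.0 - np.exp(-0.1 * 0.74), rel=1e-12)

    def test_combined_applies_stronger_hr(self, policy):
        base = 0.1
        assert effective_t2d_prob(base, 2, 3, policy) == pytest.approx(
            apply_hazard_ratio(base, 0.51)
        )

    def test_effect_expires_after_duration(self, policy):
        assert effective_t2d_prob(0.1, 1, 15, policy) == 0.1
        assert effective_t2d_prob(0.1, 1, 16, policy) == 0.1
        assert effective_t2d_prob(0.1, 1, 14.0, policy) < 0.1


class TestStep:
    def test_zero_probabilities_keep_state(self):
        for state in (HealthState.HEALTHY, HealthState.T2D, HealthState.T2D_COMPLICATIONS):
            assert step(state, 0.0, 0.0, 0.0, 0.5, 0.5) == state

    def test_certain_death(self):
        assert step(HealthState.HEALTHY, 1.0, 0.0, 0.0, 0.99, 0.5) == HealthState.DEAD

    def test_dead_cannot_be_stepped(self):
        with pytest.raises(ValueError):
            step(HealthState.DEAD, 0.1, 0.0, 0.0, 0.5, 0.5)

    def test_death_drawn_before_progression(self):
        # the same uniform below both thresholds resolves to death
        assert step(HealthState.HEALTHY, 0.3, 0.9, 0.0, 0.2, 0.2) == HealthState.DEAD

    def test_empirical_frequencies_match_exact_enumeration(self):
        # death first, then onset for survivors:
        # P(DEAD) = 0.1; P(T2D) = 0.9 * 0.2 = 0.18; P(HEALTHY) = 0.72
        rng = np.random.default_rng(77)
        n = 10_000
        outcomes = np.array(
            [
                step(HealthState.HEALTHY, 0.1, 0.2, 0.0, rng.random(), rng.random())
                for _ in range(n)
            ]
        )
        for state, p_exact in (
            (HealthState.DEAD, 0.1),
            (HealthState.T2D, 0.9 * 0.2),
            (HealthState.HEALTHY, 0.9 * 0.8),
        ):
            freq = (outcomes == state).mean()
            se = np.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(freq - p_exact) < 3 * se, state


class TestSimulateIndividual:
    def null_models(self, models, zero_life_table, null_hazard_model):
        return dataclasses.replace(
            models,
            t2d_truth=null_hazard_model,
            complications=null_hazard_model,
            life_table=zero_life_table,
        )

    def person(self, **kw):
        base = dict(
            id=0, age=60, sex=1, findrisc=12, prs=0.5,
            risk10_no_prs=0.15, risk10_with_prs=0.25,
        )
        base.update(kw)
        return pd.Series(base)

    def streams_for(self, person, seed=1):
        s = draw_streams(1, 100 - int(person["age"]), seed)
        return (s.death[0], s.prog[0], s.uptake[0])

    def test_zero_hazards_survive_healthy_to_100(
        self, models, base_params, policy, zero_life_table, null_hazard_model
    ):
        ms = self.null_models(models, zero_life_table, null_hazard_model)
        person = self.person()
        traj = simulate_individual(
            person, Strategy.USUAL, ms, base_params, policy, self.streams_for(person)
        )
        assert len(traj) == 40  # ages 60..99
        assert all(s == HealthState.HEALTHY for s in traj.states)
        assert traj.ages[-1] == 99

    def test_transitions_follow_the_state_diagram(self, models, base_params, policy):
        allowed = {
            HealthState.HEALTHY: {HealthState.HEALTHY, HealthState.T2D, HealthState.DEAD},
            HealthState.T2D: {HealthState.T2D, HealthState.T2D_COMPLICATIONS, HealthState.DEAD},
            HealthState.T2D_COMPLICATIONS: {HealthState.T2D_COMPLICATIONS, HealthState.DEAD},
        }
        for seed in range(30):
            person = self.person()
            traj = simulate_individual(
                person, Strategy.PRS, models, base_params, policy,
                self.streams_for(person, seed),
            )
            chain = [HealthState.HEALTHY] + list(traj.states)
            for a, b in zip(chain, chain[1:]):
                assert b in allowed[a], (a, b)
            # absorbing death: at most one final DEAD record
            assert [s == HealthState.DEAD for s in traj.states].count(True) <= 1

    def test_complication_clock_starts_at_onset(self, models, base_params, policy):
        for seed in range(40):
            person = self.person()
            traj = simulate_individual(
                person, Strategy.USUAL, models, base_params, policy,
                self.streams_for(person, seed),
            )
            onset_years = [
                i for i, s in enumerate(traj.states) if s == HealthState.T2D
            ]
            if onset_years:
                k = onset_years[0]
                assert traj.years_since_onset[k] == 0
                if k + 1 < len(traj) and traj.states[k + 1] != HealthState.DEAD:
                    assert traj.years_since_onset[k + 1] == 1

    def test_qalys_bounded_by_life_years(self, models, base_params, policy):
        person = self.person()
        traj = simulate_individual(
            person, Strategy.PRS, models, base_params, policy, self.streams_for(person, 9)
        )
        _, qaly = aggregate_trajectory(traj, DiscountSpec(0.0))
        life_years = sum(s != HealthState.DEAD for s in traj.states)
        assert qaly <= life_years


class TestRunArm:
    def test_cohort_of_one_matches_individual(self, models, base_params, policy):
        person = pd.DataFrame(
            [dict(id=0, age=62, sex=0, findrisc=14, prs=1.2,
                  risk10_no_prs=0.15, risk10_with_prs=0.22)]
        )
        streams = draw_streams(1, 38, 5)
        arm = run_arm(person, Strategy.PRS, models, base_params, policy, streams)
        traj = simulate_individual(
            person.iloc[0], Strategy.PRS, models, base_params, policy,
            (streams.death[0], streams.prog[0], streams.uptake[0]),
        )
        cost, qaly = aggregate_trajectory(traj, DiscountSpec(0.03))
        assert arm.mean_cost == pytest.approx(cost, abs=1e-9)
        assert arm.mean_qaly == pytest.approx(qaly, abs=1e-9)

    def test_vectorized_agrees_with_reference(
        self, models, base_params, policy, target_cohort, shared_streams
    ):
        cohort = target_cohort.head(60).copy()
        streams_sub = dataclasses.replace(
            shared_streams,
            death=shared_streams.death[:60],
            prog=shared_streams.prog[:60],
            uptake=shared_streams.uptake[:60],
        )
        arm = run_arm(cohort, Strategy.PRS, models, base_params, policy, streams_sub)
        for i in range(len(cohort)):
            traj = simulate_individual(
                cohort.iloc[i], Strategy.PRS, models, base_params, policy,
                (streams_sub.death[i], streams_sub.prog[i], streams_sub.uptake[i]),
            )
            cost, qaly = aggregate_trajectory(traj, DiscountSpec(0.03))
            assert arm.per_individual["cost"].iloc[i] == pytest.approx(cost, abs=1e-8)
            assert arm.per_individual["qaly"].iloc[i] == pytest.approx(qaly, abs=1e-10)

    def test_empty_cohort_is_an_error(self, models, base_params, policy):
        with pytest.raises(ValueError, match="empty"):
            run_arm(pd.DataFrame(columns=["age", "sex"]), Strategy.USUAL, models,
                    base_params, policy, 1)

    def test_doubling_costs_doubles_mean_cost(
        self, models, base_params, policy, target_cohort, shared_streams
    ):
        import dataclasses as dc

        doubled_costs = dc.replace(
            base_params.costs,
            **{f.name: 2 * getattr(base_params.costs, f.name)
               for f in dc.fields(base_params.costs)},
        )
        doubled = dc.replace(base_params, costs=doubled_costs)
        a = run_arm(target_cohort, Strategy.PRS, models, base_params, policy, shared_streams)
        b = run_arm(target_cohort, Strategy.PRS, models, doubled, policy, shared_streams)
        assert b.mean_cost == pytest.approx(2 * a.mean_cost, rel=1e-12)
        assert b.mean_qaly == a.mean_qaly

    def test_years_in_states_conserve(self, models, base_params, policy,
                                      target_cohort, shared_streams):
        arm = run_arm(target_cohort, Strategy.USUAL, models, base_params, policy,
                      shared_streams)
        pi = arm.per_individual
        assert (pi["years_t2d_free"] <= pi["years_complication_free"]).all()
        assert (pi["years_complication_free"] <= pi["years_alive"]).all()
        assert (pi["qaly"] <= pi["years_alive"]).all()

    def test_prs_test_price_linearity(self, models, base_params, policy,
                                      target_cohort, shared_streams):
        import dataclasses as dc

        delta = 137.0
        bumped = dc.replace(
            base_params, costs=dc.replace(base_params.costs, prs_test=50.0 + delta)
        )
        a = run_arm(target_cohort, Strategy.PRS, models, base_params, policy, shared_streams)
        b = run_arm(target_cohort, Strategy.PRS, models, bumped, policy, shared_streams)
        assert b.mean_cost - a.mean_cost == pytest.approx(delta, abs=1e-9)
        # the usual arm never pays for the test
        u_a = run_arm(target_cohort, Strategy.USUAL, models, base_params, policy, shared_streams)
        u_b = run_arm(target_cohort, Strategy.USUAL, models, bumped, policy, shared_streams)
        assert u_b.mean_cost == u_a.mean_cost


class TestNullPrsEquivalence:
    def test_arms_identical_when_prs_is_uninformative(self, models, base_params, policy):
        import dataclasses as dc

        truth = models.t2d_truth.with_coefficient("prs", 0.0)
        null_models = dc.replace(
            models,
            t2d_truth=truth,
            t2d_screen_no_prs=models.t2d_screen_no_prs,
            t2d_screen_with_prs=truth,
        )
        free_test = dc.replace(
            base_params, costs=dc.replace(base_params.costs, prs_test=0.0)
        )
        from t2dsim.config import RunConfig
        from t2dsim.psa_decision import _make_target_cohort

        cohort = _make_target_cohort(
            RunConfig(seed=23, n_per_arm=500), null_models, 500, seed=23
        )
        usual, prs = run_pair(cohort, null_models, free_test, policy, 99)
        assert usual.mean_cost == prs.mean_cost
        assert usual.mean_qaly == prs.mean_qaly
        assert usual.death_fraction == prs.death_fraction
        assert prs.reclassified_fraction == 0.0


class TestReclassification:
    def test_counting(self):
        cohort = pd.DataFrame({"risk10_with_prs": [0.21, 0.15, 0.25, 0.19]})
        assert reclassification_rate(cohort) == 0.5

    def test_all_above(self):
        assert reclassification_rate(pd.DataFrame({"risk10_with_prs": [0.3, 0.9]})) == 1.0

    def test_empty(self):
        assert reclassification_rate(pd.DataFrame({"risk10_with_prs": []})) == 0.0
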