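"""Markov engine: conversions, persistence, transitions, cohort recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteocea import (
    OFF_TREATMENT,
    TREATMENT,
    StateSpace,
    arm_multiplier,
    build_transition_row,
    correction_factor,
    cycle_mortality,
    default_parameters,
    effect_multiplier,
    load_parameters,
    persistence_profile,
    rate_to_probability,
    run_cohort,
)
from osteocea.engine import PersistenceProfile, build_transition_matrix, \
    _cycle_inputs
from osteocea.microsim import random_parameters


class TestRateToProbability:
    def test_published_discontinuation_probability(self):
        # 0.317/patient-year over a 6-month cycle prints as 14.7%
        assert round(rate_to_probability(0.317, 0.5), 3) == 0.147

    def test_closed_form(self):
        assert rate_to_probability(0.017, 0.5) == pytest.approx(
            1 - math.exp(-0.0085), abs=1e-12)

    def test_zero_rate(self):
        assert rate_to_probability(0.0, 0.5) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 0.5)

    @given(rate=st.floats(0, 10), duration=st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_is_a_probability(self, rate, duration):
        p = rate_to_probability(rate, duration)
        assert 0.0 <= p <= 1.0
        if rate * duration < 30:  # below float saturation of 1 - e^-x
            assert p < 1.0


class TestEffectMultiplier:
    def test_persistent_gets_full_hazard_ratio(self):
        assert effect_multiplier(0.62, "persistent") == 0.62

    def test_off_has_no_residual_effect(self):
        assert effect_multiplier(0.62, "off") == 1.0

    def test_first_offset_cycle_keeps_full_benefit(self):
        # the linear decline starts when drug coverage ends
        assert effect_multiplier(0.62, 1) == pytest.approx(0.62)

    def test_linear_decline_across_offset(self):
        mults = [effect_multiplier(0.62, k) for k in range(1, 5)]
        assert mults == pytest.approx([0.62, 0.715, 0.81, 0.905])
        steps = np.diff(mults)
        assert np.allclose(steps, steps[0])

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            effect_multiplier(0.62, "sometimes")


class TestPersistenceProfile:
    def test_everyone_persistent_through_first_two_cycles(self, params):
        prof = persistence_profile(params.settings)
        assert prof.persistent[0] == 1.0
        assert prof.persistent[1] == 1.0

    def test_per_cycle_decay_from_cycle_two(self, params):
        prof = persistence_profile(params.settings)
        p_disc = rate_to_probability(0.317, 0.5)
        assert prof.persistent[2] == pytest.approx(1 - p_disc)
        assert prof.persistent[5] == pytest.approx((1 - p_disc) ** 4)

    def test_no_one_persistent_after_course_ends(self, params):
        prof = persistence_profile(params.settings)
        assert np.all(prof.persistent[10:] == 0.0)

    def test_weights_always_sum_to_one(self, params):
        prof = persistence_profile(params.settings)
        totals = prof.persistent + prof.offset.sum(axis=1) + prof.off
        assert np.allclose(totals, 1.0, atol=1e-12)
        assert np.all(prof.offset >= 0) and np.all(prof.off >= 0)

    def test_completers_enter_offset_at_course_end(self, params):
        prof = persistence_profile(params.settings)
        # all remaining persistent patients at cycle 9 become offset k=1 at 10
        assert prof.offset[10, 0] == pytest.approx(prof.persistent[9])

    @given(rate=st.floats(0.0, 3.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_for_any_discontinuation_rate(self, rate):
        p = load_parameters({"settings": {"annual_discontinuation_rate": rate}})
        prof = persistence_profile(p.settings)
        totals = prof.persistent + prof.offset.sum(axis=1) + prof.off
        assert np.allclose(totals, 1.0, atol=1e-9)

    def test_zero_rate_means_full_persistence(self):
        p = load_parameters({"settings": {"annual_discontinuation_rate": 0.0}})
        prof = persistence_profile(p.settings)
        assert np.all(prof.persistent[:10] == 1.0)
        assert prof.offset[10, 0] == 1.0


class TestArmMultiplier:
    def test_off_treatment_single_dose_covers_first_cycle_only(self, params):
        assert arm_multiplier("hip", 0, OFF_TREATMENT, None, params) == 0.62
        assert arm_multiplier("hip", 5, OFF_TREATMENT, None, params) == 1.0

    def test_weighted_mean_over_strata(self, params):
        n = params.settings.n_cycles
        half = PersistenceProfile(np.full(n, 0.5), np.zeros((n, 4)),
                                  np.full(n, 0.5))
        m = arm_multiplier("hip", 3, TREATMENT, half, params)
        assert m == pytest.approx(0.5 * 0.62 + 0.5 * 1.0)

    def test_nondecreasing_and_reaches_one(self, params):
        prof = persistence_profile(params.settings)
        mults = [arm_multiplier("hip", c, TREATMENT, prof, params)
                 for c in range(params.settings.n_cycles)]
        assert np.all(np.diff(mults) >= -1e-12)
        # four cycles after the course ends everyone is beyond the offset
        assert mults[14] == pytest.approx(1.0)
        assert mults[0] == 0.62


class TestCycleMortality:
    def test_well_state(self, params):
        space = StateSpace(params)
        assert cycle_mortality(space, "well", 77) == pytest.approx(
            1 - (1 - 0.041) ** 0.5, abs=1e-9)

    def test_first_year_hip_relative_risk(self, params):
        space = StateSpace(params)
        expected = 1 - math.exp(-(-math.log(1 - 0.041)) * 1.57 * 0.5)
        assert cycle_mortality(space, "hip_1", 77) == pytest.approx(expected)

    def test_subsequent_hip_relative_risk_within_window(self, params):
        space = StateSpace(params)
        expected = 1 - math.exp(-(-math.log(1 - 0.089)) * 1.37 * 0.5)
        assert cycle_mortality(space, "hip_16", 85) == pytest.approx(expected)

    def test_beyond_excess_window_reverts_to_well(self, params):
        space = StateSpace(params)
        for age in (77, 85, 95):
            assert cycle_mortality(space, "post_hip", age) == pytest.approx(
                cycle_mortality(space, "well", age))


class TestTransitions:
    def test_dead_is_absorbing(self, params):
        space = StateSpace(params)
        row = build_transition_row(space, "dead", 3, 78.5, TREATMENT)
        assert row == {"dead": 1.0}

    @pytest.mark.parametrize("arm", [TREATMENT, OFF_TREATMENT])
    @pytest.mark.parametrize("cycle,age", [(0, 77.0), (7, 80.5), (30, 92.0)])
    def test_rows_are_stochastic(self, params, arm, cycle, age):
        space = StateSpace(params)
        pers = persistence_profile(params.settings)
        q, p_frac = _cycle_inputs(space, cycle, age, arm,
                                  pers if arm == TREATMENT else None)
        T = build_transition_matrix(space, q, p_frac)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(T >= 0)

    def test_well_to_hip_probability_off_arm_first_cycle(self, params):
        space = StateSpace(params)
        row = build_transition_row(space, "well", 0, 77.0, OFF_TREATMENT)
        assert row["hip_1"] == pytest.approx(
            1 - math.exp(-0.017 * 0.62 * 0.5), abs=1e-9)

    def test_severity_hierarchy(self, params):
        space = StateSpace(params)
        vert_row = build_transition_row(space, "vertebral_3", 5, 79.5,
                                        OFF_TREATMENT)
        assert "hip_1" in vert_row          # hip allowed from vertebral states
        assert "other_1" not in vert_row    # "other" barred
        assert "vertebral_1" not in vert_row  # re-fracture not modelled
        hip_row = build_transition_row(space, "hip_2", 5, 79.5, OFF_TREATMENT)
        assert "hip_1" in hip_row           # subsequent hip fracture allowed
        assert "vertebral_1" not in hip_row
        assert "other_1" not in hip_row

    def test_tunnels_advance_and_other_returns_to_well(self, params):
        space = StateSpace(params)
        row = build_transition_row(space, "hip_16", 9, 81.5, OFF_TREATMENT)
        assert "post_hip" in row
        row = build_transition_row(space, "other_2", 9, 81.5, OFF_TREATMENT)
        assert "well" in row and "other_1" not in row


class TestRunCohort:
    def test_null_dynamics_stay_well(self):
        p = load_parameters({
            "rates": {"hip": 0.0, "vertebral": 0.0, "other": 0.0},
            "mortality": {"well_annual": {70: 0.0, 80: 0.0, 90: 0.0}},
        })
        trace = run_cohort(p, OFF_TREATMENT)
        assert np.all(trace.occupancy[:, trace.space.well] == 1.0)
        assert np.all(trace.incident == 0.0)

    def test_hip_tunnel_occupancy_matches_closed_form(self):
        # no mortality, hip fractures only, no treatment effect: each cycle a
        # fraction p of everyone (well or hip track, via re-fracture) enters
        # hip year 1, so tunnel t holds p(1-p)^(t-1) once filled
        p = load_parameters({
            "rates": {"hip": 0.02, "vertebral": 0.0, "other": 0.0},
            "effect": {"hr_hip": 1.0, "hr_vertebral": 1.0,
                       "hr_nonvertebral": 1.0},
            "mortality": {"well_annual": {70: 0.0, 80: 0.0, 90: 0.0}},
        })
        trace = run_cohort(p, OFF_TREATMENT)
        prob = rate_to_probability(0.02, 0.5)
        space = trace.space
        for t in (1, 2, 5, 16):
            expected = prob * (1 - prob) ** (t - 1)
            assert trace.occupancy[30, space.index[f"hip_{t}"]] == \
                pytest.approx(expected, rel=1e-12)
        assert np.allclose(trace.incident[1:, 0], prob)

    def test_two_cycle_occupancy_matches_hand_arithmetic(self):
        # pure death process: survival is (1-q)^c with q = 1-(1-p_annual)^0.5
        p = load_parameters({
            "rates": {"hip": 0.0, "vertebral": 0.0, "other": 0.0},
            "mortality": {"well_annual": {70: 0.1, 80: 0.1, 90: 0.1}},
        })
        trace = run_cohort(p, OFF_TREATMENT)
        q = 1 - 0.9 ** 0.5
        assert trace.occupancy[1, trace.space.well] == pytest.approx(1 - q)
        assert trace.occupancy[2, trace.space.well] == pytest.approx((1 - q) ** 2)
        assert trace.occupancy[2, trace.space.dead] == pytest.approx(
            1 - (1 - q) ** 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_and_dead_monotonicity(self, seed):
        p = random_parameters(seed)
        for arm in (TREATMENT, OFF_TREATMENT):
            trace = run_cohort(p, arm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            dead = trace.occupancy[:, trace.space.dead]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all(trace.occupancy >= -1e-15)

    def test_base_case_conservation(self, base_traces):
        for trace in base_traces.values():
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(trace.occupancy[:, trace.space.dead])
                          >= -1e-15)

    @pytest.mark.parametrize("seed", [None, 0, 1, 2])
    def test_treatment_dominance_on_cumulative_incidence(self, seed):
        # total incidence (Markov-visible plus correction-factor events):
        # the visible count alone can cross over, because the arm with more
        # hip-state occupancy has more of its vertebral burden hidden
        p = default_parameters() if seed is None else random_parameters(seed)
        if any(params_hr >= 1.0 for params_hr in (
                p.effect.hr_hip.value, p.effect.hr_vertebral.value,
                p.effect.hr_nonvertebral.value)):
            p = load_parameters({**p.to_dict(),
                                 "effect": {"hr_hip": 0.7, "hr_vertebral": 0.7,
                                            "hr_nonvertebral": 0.7}})
        cum = {}
        for arm in (TREATMENT, OFF_TREATMENT):
            trace = run_cohort(p, arm)
            shadow = correction_factor(trace, p)
            cum[arm] = np.cumsum(trace.incident + shadow.events, axis=0)
        assert np.all(cum[TREATMENT] <= cum[OFF_TREATMENT] + 1e-12)

    def test_null_effect_makes_arms_identical(self):
        p = load_parameters({"effect": {"hr_hip": 1.0, "hr_vertebral": 1.0,
                                        "hr_nonvertebral": 1.0}})
        tr_t = run_cohort(p, TREATMENT)
        tr_o = run_cohort(p, OFF_TREATMENT)
        assert np.allclose(tr_t.occupancy, tr_o.occupancy, atol=1e-14)
        assert np.allclose(tr_t.incident, tr_o.incident, atol=1e-14)


class TestCorrectionFactor:
    def test_zero_rates_give_zero_shadow_events(self):
        p = load_parameters({"rates": {"hip": 0.0, "vertebral": 0.0,
                                       "other": 0.0}})
        trace = run_cohort(p, OFF_TREATMENT)
        shadow = correction_factor(trace, p)
        assert shadow.total_cost == 0.0
        assert shadow.total_qaly_loss == 0.0
        assert np.all(shadow.events == 0.0)

    def test_events_proportional_to_hip_occupancy(self, params, base_traces):
        trace = base_traces[OFF_TREATMENT]
        shadow = correction_factor(trace, params)
        space = trace.space
        hip_occ = trace.occupancy[:-1, space.hip_group].sum(axis=1)
        expected = hip_occ * trace.fracture_prob[:, 1]
        assert np.allclose(shadow.events[:, 1], expected)
        assert np.all(shadow.events[:, 0] == 0.0)  # no overlooked hips

    def test_everything_nonnegative(self, params, base_traces):
        for trace in base_traces.values():
            shadow = correction_factor(trace, params)
            for arr in (shadow.events, shadow.cost, shadow.qaly_loss,
                        shadow.excess_deaths):
                assert np.all(arr >= 0.0)

    def test_monotone_in_baseline_rates(self, params):
        base = correction_factor(run_cohort(params, OFF_TREATMENT), params)
        higher_p = load_parameters({"rates": {"hip": 0.017, "vertebral": 0.03,
                                              "other": 0.008}})
        higher = correction_factor(run_cohort(higher_p, OFF_TREATMENT),
                                   higher_p)
        assert higher.events.sum() > base.events.sum()
        assert higher.total_cost > base.total_cost
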