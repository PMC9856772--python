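"""Cohort propagation, discounted accounting and incremental comparison."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfucea import (
    GWC,
    ON101,
    ArmOutcome,
    Dominance,
    HealthState,
    ParameterSet,
    StrategyConfig,
    TransitionSpec,
    accumulate_outcomes,
    build_transition_matrix,
    compare_strategies,
    compute_icer,
    discount_factor,
    generate_random_model,
    run_cohort,
)
from dfucea.states import STATE_INDEX, STATES

U = STATE_INDEX[HealthState.UDFU]
D = STATE_INDEX[HealthState.DEATH]


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [(0.03, 0, 1.0), (0.03, 12, 0.9708737864), (0.0, 60, 1.0)],
    )
    def test_known_values(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-10)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)

    def test_annual_step_mode_is_flat_within_a_year(self):
        assert discount_factor(0.03, 11, annual_step=True) == 1.0
        assert discount_factor(0.03, 12, annual_step=True) == pytest.approx(1 / 1.03)


class TestRunCohort:
    def test_identity_matrix_is_static(self):
        trace = run_cohort(np.eye(6), HealthState.UDFU, 60)
        assert (trace.occupancy[:, U] == 1.0).all()

    def test_instant_death_absorbs_from_cycle_one(self):
        m = np.zeros((6, 6))
        m[:, D] = 1.0
        trace = run_cohort(m, HealthState.UDFU, 12)
        assert (trace.occupancy[1:, D] == 1.0).all()

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(Exception):
            run_cohort(np.full((6, 6), 0.5), HealthState.UDFU, 10)

    @pytest.mark.parametrize("seed", range(25))
    def test_occupancy_matches_matrix_power_oracle(self, seed):
        ps = generate_random_model(seed)
        m = build_transition_matrix(ps, GWC)
        trace = run_cohort(m, HealthState.UDFU, 24)
        v0 = np.zeros(6)
        v0[U] = 1.0
        for t in (1, 7, 24):
            expected = v0 @ np.linalg.matrix_power(m, t)
            assert np.allclose(trace.occupancy[t], expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_invariants(self, seed):
        ps = generate_random_model(seed)
        m = build_transition_matrix(ps, ON101)
        trace = run_cohort(m, HealthState.UDFU, 30)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        # flows are consistent with occupancy on both margins
        assert np.allclose(trace.flows.sum(axis=2), trace.occupancy[:-1], atol=1e-12)
        assert np.allclose(trace.flows.sum(axis=1), trace.occupancy[1:], atol=1e-12)
        death = trace.occupancy[:, D]
        assert (np.diff(death) >= -1e-12).all()


def _single_state_params(utility=0.84, discount=0.0, cycles=12):
    return ParameterSet(
        transitions=(),
        utilities={s: utility for s in STATES},
        state_costs={s: 0.0 for s in STATES},
        event_costs={},
        drug_cost_monthly=0.0,
        healing_or=2.0,
        discount_rate_annual=discount,
        horizon_cycles=cycles,
        initial_state=HealthState.HEALED,
    )


class TestAccumulateOutcomes:
    def test_zero_costs_and_utilities_leave_only_life_years(self):
        ps = _single_state_params(utility=0.0)
        m = build_transition_matrix(ps, GWC)
        trace = run_cohort(m, ps.initial_state, 12)
        out = accumulate_outcomes(trace, ps, GWC)
        assert out.total_cost == 0.0
        assert out.qalys == 0.0
        assert out.life_years == pytest.approx(1.0)

    def test_one_year_healed_at_constant_utility(self):
        ps = _single_state_params(utility=0.84)
        m = build_transition_matrix(ps, GWC)
        trace = run_cohort(m, ps.initial_state, 12)
        out = accumulate_outcomes(trace, ps, GWC)
        assert out.qalys == pytest.approx(0.84, abs=1e-12)

    def test_cost_components_are_additive(self, params, strategies):
        _, intervention = strategies
        m = build_transition_matrix(params, intervention)
        trace = run_cohort(m, params.initial_state, params.horizon_cycles)
        full = accumulate_outcomes(trace, params, intervention)
        assert full.total_cost == pytest.approx(sum(full.cost_components.values()))
        # switching a component off removes exactly its contribution
        no_events = dataclasses.replace(params, event_costs={})
        out = accumulate_outcomes(trace, no_events, intervention)
        assert full.total_cost - out.total_cost == pytest.approx(
            full.cost_components["event"]
        )
        no_drug = StrategyConfig(label="x", apply_healing_or=False)
        out = accumulate_outcomes(trace, params, no_drug)
        assert full.cost_components["drug"] > 0
        assert out.cost_components["drug"] == 0.0

    def test_drug_duration_cap_reduces_drug_cost(self, params):
        capped = StrategyConfig(
            label="capped",
            apply_healing_or=True,
            drug_duration_cap_cycles=4,
        )
        m = build_transition_matrix(params, capped)
        trace = run_cohort(m, params.initial_state, params.horizon_cycles)
        capped_out = accumulate_outcomes(trace, params, capped)
        full_out = accumulate_outcomes(
            trace, params, StrategyConfig(label="u", apply_healing_or=True)
        )
        assert 0 < capped_out.cost_components["drug"] < full_out.cost_components["drug"]

    def test_discounting_only_shrinks_qalys(self, params, strategies):
        comparator, _ = strategies
        m = build_transition_matrix(params, comparator)
        trace = run_cohort(m, params.initial_state, params.horizon_cycles)
        discounted = accumulate_outcomes(trace, params, comparator)
        undiscounted = accumulate_outcomes(
            trace, params.with_overrides(discount_rate_annual=0.0), comparator
        )
        assert discounted.qalys < undiscounted.qalys
        assert discounted.qalys <= discounted.life_years

    def test_missing_utility_is_a_configuration_error(self, params, strategies):
        comparator, _ = strategies
        broken = dataclasses.replace(
            params, utilities={HealthState.HEALED: 0.84, HealthState.DEATH: 0.0}
        )
        m = build_transition_matrix(params, comparator)
        trace = run_cohort(m, params.initial_state, 12)
        with pytest.raises(ValueError, match="utilit"):
            accumulate_outcomes(trace, broken, comparator)

    def test_longer_horizon_never_reduces_cost_or_death(self, params, strategies):
        comparator, _ = strategies
        m = build_transition_matrix(params, comparator)
        prev_cost, prev_death = 0.0, 0.0
        for horizon in (12, 24, 48, 60):
            trace = run_cohort(m, params.initial_state, horizon)
            out = accumulate_outcomes(trace, params, comparator)
            assert out.total_cost >= prev_cost - 1e-9
            death = trace.occupancy[-1, D]
            assert death >= prev_death - 1e-12
            prev_cost, prev_death = out.total_cost, death


def _arm(cost, qalys, label="arm"):
    return ArmOutcome(
        strategy=label,
        total_cost=cost,
        life_years=qalys + 1.0,
        qalys=qalys,
        cost_components={},
        mean_months_in_state={},
        cumulative_probability={},
    )


class TestComputeIcer:
    def test_published_rounding_example(self):
        res = compute_icer(_arm(9781, 3.7402, "a"), _arm(9210, 3.7019, "b"))
        assert res.delta_cost == pytest.approx(571)
        assert res.delta_qalys == pytest.approx(0.0383)
        assert res.icer == pytest.approx(14908.6, abs=0.1)
        assert res.dominance is Dominance.RATIO

    def test_identical_arms_flagged_undefined(self):
        res = compute_icer(_arm(100, 1.0, "a"), _arm(100, 1.0, "b"))
        assert res.icer is None
        assert res.dominance is Dominance.UNDEFINED

    def test_cheaper_and_better_is_dominant_not_a_negative_ratio(self):
        res = compute_icer(_arm(900, 1.1, "a"), _arm(1000, 1.0, "b"))
        assert res.icer is None
        assert res.dominance is Dominance.DOMINANT

    def test_costlier_and_worse_is_dominated(self):
        res = compute_icer(_arm(1100, 0.9, "a"), _arm(1000, 1.0, "b"))
        assert res.dominance is Dominance.DOMINATED

    def test_nmb_is_wtp_times_qalys_minus_cost(self):
        res = compute_icer(_arm(500, 2.0, "a"), _arm(400, 1.5, "b"), wtp_list=(1000.0,))
        assert res.nmb[1000.0]["a"] == pytest.approx(1000 * 2.0 - 500)
        assert res.nmb_difference(1000.0) == pytest.approx(500 - 100)


@given(seed=st.integers(0, 500))
def test_random_models_yield_finite_outcomes(seed):
    ps = generate_random_model(seed)
    res = compare_strategies(ps)
    for arm in (res.comparator, res.intervention):
        assert np.isfinite(arm.total_cost) and arm.total_cost >= 0
        assert np.isfinite(arm.qalys) and 0 <= arm.qalys <= arm.life_years + 1e-9
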