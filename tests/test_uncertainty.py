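"""PSA sampling, CEAC identities, tornado and bisection analyses."""

import dataclasses

import numpy as np
import pytest

from dfucea import (
    ModelValidationError,
    ParameterDistribution,
    break_even_multiplier,
    compare_strategies,
    compute_ceac,
    distributions_for,
    one_way_dsa,
    run_psa,
    sample_parameter,
    two_way_threshold,
)
from dfucea.modelfile import ValueRecord


class TestSampleParameter:
    def test_uniform_respects_bounds_and_mean(self):
        d = ParameterDistribution("u", "uniform", 0.84, 0.756, 0.924)
        rng = np.random.default_rng(0)
        x = sample_parameter(d, rng, 100_000)
        assert x.min() >= 0.756 and x.max() <= 0.924
        se = (0.924 - 0.756) / np.sqrt(12) / np.sqrt(x.size)
        assert abs(x.mean() - 0.84) < 3 * se

    def test_triangular_mean_is_average_of_vertices(self):
        d = ParameterDistribution("t", "triangular", 608, 304, 912)
        rng = np.random.default_rng(1)
        x = sample_parameter(d, rng, 100_000)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - (304 + 608 + 912) / 3) < 3 * se

    def test_beta_moments_match_range_convention(self):
        d = ParameterDistribution("b", "beta", 0.259, 0.1295, 0.3885)
        rng = np.random.default_rng(2)
        x = sample_parameter(d, rng, 100_000)
        assert ((x >= 0) & (x <= 1)).all()
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 0.259) < 3 * se
        target_sd = (0.3885 - 0.1295) / 3.92
        assert x.std() == pytest.approx(target_sd, rel=0.02)

    def test_lognormal_median_is_base(self):
        d = ParameterDistribution("l", "lognormal", 2.30, 1.15, 3.45)
        rng = np.random.default_rng(3)
        x = sample_parameter(d, rng, 100_000)
        assert (x > 0).all()
        assert np.median(x) == pytest.approx(2.30, rel=0.02)

    def test_degenerate_range_returns_constant(self):
        d = ParameterDistribution("c", "triangular", 5.0, 5.0, 5.0)
        rng = np.random.default_rng(4)
        assert sample_parameter(d, rng) == 5.0

    def test_infeasible_beta_moments_name_the_parameter(self):
        d = ParameterDistribution("edge probability", "beta", 0.5, -1.5, 2.5)
        with pytest.raises(ModelValidationError, match="edge probability"):
            sample_parameter(d, np.random.default_rng(0))


def _degenerate(defn):
    """Collapse every distribution to a point mass at its base value."""
    def point(rec):
        return ValueRecord(rec.value, rec.value, rec.value, rec.distribution)

    return dataclasses.replace(
        defn,
        transitions=tuple(
            dataclasses.replace(t, low=t.value, high=t.value) for t in defn.transitions
        ),
        utilities={s: point(r) for s, r in defn.utilities.items()},
        state_costs={s: point(r) for s, r in defn.state_costs.items()},
        event_costs=tuple(
            dataclasses.replace(e, record=point(e.record)) for e in defn.event_costs
        ),
        initial_event=point(defn.initial_event),
        drug=point(defn.drug),
        effect=point(defn.effect),
    )


class TestRunPsa:
    def test_same_seed_reproduces_identically(self, defn):
        a = run_psa(defn, 50, seed=9)
        b = run_psa(defn, 50, seed=9)
        assert a.iterations.equals(b.iterations)

    def test_point_mass_distributions_collapse_to_base_case(self, defn, base_result):
        psa = run_psa(_degenerate(defn), 20, seed=0)
        assert psa.n_resampled == 0
        assert np.allclose(psa.iterations["delta_cost"], base_result.delta_cost)
        assert np.allclose(psa.iterations["delta_qaly"], base_result.delta_qalys)
        assert psa.mean_icer() == pytest.approx(base_result.icer)

    def test_ceac_endpoint_identities(self, defn):
        psa = run_psa(defn, 400, seed=13)
        dc = psa.iterations["delta_cost"].to_numpy()
        dq = psa.iterations["delta_qaly"].to_numpy()
        ceac = compute_ceac(psa, (0.0, 1e12))
        p = ceac["probability_cost_effective"].to_numpy()
        assert p[0] == pytest.approx((dc < 0).mean())
        assert p[1] == pytest.approx((dq > 0).mean())

    def test_empty_wtp_grid_rejected(self, defn):
        psa = run_psa(defn, 5, seed=0)
        with pytest.raises(ValueError):
            compute_ceac(psa, ())

    def test_model_distributions_cover_every_ranged_parameter(self, defn):
        dists = distributions_for(defn)
        assert set(dists) == set(defn.parameter_names())
        families = {d.family for d in dists.values()}
        assert families == {"beta", "uniform", "triangular", "lognormal"}


class TestOneWayDsa:
    def test_zero_width_range_has_zero_span(self, defn):
        entries = one_way_dsa(defn, {"monthly drug cost": (608.0, 608.0)})
        assert entries[0].span_pct_of_base == pytest.approx(0.0, abs=1e-9)
        assert not entries[0].flagged

    def test_dead_parameter_leaves_icer_unchanged(self, defn):
        # the postamputation->gangrene transition is excluded from the
        # calibrated matrix, so nothing ever flows into its event cost
        entries = one_way_dsa(
            defn,
            {"event cost: Hospitalization for postamputation gangrene": (0.0, 1e6)},
        )
        assert entries[0].span_pct_of_base == pytest.approx(0.0, abs=1e-6)

    def test_unknown_parameter_rejected(self, defn):
        with pytest.raises(ModelValidationError, match="unknown"):
            one_way_dsa(defn, {"nonexistent": (0, 1)})

    def test_entries_sorted_by_descending_span(self, defn):
        entries = one_way_dsa(defn)
        spans = [e.span_pct_of_base for e in entries]
        assert spans == sorted(spans, reverse=True)


class TestBisectionAnalyses:
    def test_break_even_root_verified_by_sign_change(self, defn):
        res = break_even_multiplier(defn, "cost_saving", tol=0.001)
        assert res.status == "root"

        def delta_cost(mult):
            params = defn.parameter_set(
                {"monthly drug cost": defn.drug.value * mult}
            )
            return compare_strategies(params, defn.strategies()).delta_cost

        assert delta_cost(res.value - 0.002) < 0 < delta_cost(res.value + 0.002)

    def test_wtp_criterion_requires_wtp(self, defn):
        with pytest.raises(ValueError):
            break_even_multiplier(defn, "wtp_threshold")

    def test_unbracketed_criterion_reports_no_root(self, defn):
        res = break_even_multiplier(defn, "cost_saving", bracket=(5.0, 10.0))
        assert res.value is None
        assert res.status == "never"

    def test_two_way_threshold_monotone_in_drug_cost(self, defn):
        costs = (100.0, 304.0, 608.0, 912.0)
        res = two_way_threshold(defn, costs, (1.0, 3.45), wtp=98_361.0)
        values = [res[c].value for c in costs if res[c].status == "root"]
        assert values == sorted(values)

    def test_two_way_root_verified_by_nmb_sign_change(self, defn):
        res = two_way_threshold(defn, (608.0,), (1.0, 3.45), wtp=98_361.0)
        thr = res[608.0]
        assert thr.status == "root"

        def nmb_diff(or_value):
            params = defn.parameter_set({"healing odds ratio": or_value})
            return compare_strategies(params, defn.strategies()).nmb_difference(98_361.0)

        assert nmb_diff(thr.value - 0.01) < 0 < nmb_diff(thr.value + 0.01)

    def test_free_drug_with_any_benefit_is_always_cost_effective(self, defn):
        res = two_way_threshold(defn, (0.0,), (1.05, 3.45), wtp=98_361.0)
        assert res[0.0].status == "always"
        assert res[0.0].value == pytest.approx(1.05)
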