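"""Economic valuation: state costs, perspectives, ICER and dominance,
prevalence weighting, and ratio scenarios."""

from dataclasses import replace

import numpy as np
import pytest

import bipolarce as b
from bipolarce.economics import ArmOutcomes, PERSPECTIVES, arm_cost_totals
from bipolarce.parameters import HealthState


class TestStateCycleCost:
    @pytest.mark.parametrize("state, perspective, age, expected", [
        (HealthState.DEPRESSION, "societal", 40, 10_408.0),
        (HealthState.DEPRESSION, "healthcare", 40, 1_775.0),
        (HealthState.DEPRESSION, "societal", 70, 6_771.0),   # productivity cut at 67
        (HealthState.REMISSION, "societal", 40, 1_085.0),
        (HealthState.EPISODE, "societal", 40, 13_838.0),
        (HealthState.DEATH, "societal", 40, 0.0),
    ])
    def test_control_arm_sums(self, params, state, perspective, age, expected):
        cost = b.state_cycle_cost(state, age, "control", 0, params.costs,
                                  None, perspective)
        assert cost == pytest.approx(expected)

    def test_intervention_cost_first_cycle_only(self, params):
        kw = dict(cost_table=params.costs, intervention=params.intervention,
                  perspective="societal")
        first = b.state_cycle_cost(HealthState.REMISSION, 40, "intervention", 0, **kw)
        later = b.state_cycle_cost(HealthState.REMISSION, 40, "intervention", 1, **kw)
        assert first - later == pytest.approx(291.0)

    def test_intervention_cost_remission_scope(self, params):
        spec = replace(params.intervention, cost_states="remission")
        dep = b.state_cycle_cost(HealthState.DEPRESSION, 40, "intervention", 0,
                                 params.costs, spec, "societal")
        assert dep == pytest.approx(10_408.0)  # no add-on outside remission

    def test_healthcare_never_exceeds_societal(self, params):
        for state in (HealthState.REMISSION, HealthState.DEPRESSION,
                      HealthState.EPISODE):
            for age in (40, 70):
                hc = b.state_cycle_cost(state, age, "control", 0, params.costs,
                                        None, "healthcare")
                soc = b.state_cycle_cost(state, age, "control", 0, params.costs,
                                         None, "societal")
                assert hc <= soc


class TestArmTotals:
    def test_perspective_ordering_and_discounting(self, params, lifetable):
        for sub in params.subtypes:
            for arm in ("control", "intervention"):
                out = b.evaluate_arm(sub, params, arm, lifetable)
                assert out.costs["healthcare"] <= out.costs["societal"]
                assert out.costs_undiscounted["healthcare"] <= out.costs_undiscounted["societal"]
                for p in PERSPECTIVES:
                    assert out.costs[p] <= out.costs_undiscounted[p]
                assert out.qalys <= out.qalys_undiscounted
                assert out.life_years <= out.life_years_undiscounted

    def test_productivity_stops_at_retirement(self, params, lifetable):
        young = replace(params.settings, horizon=20, start_age=40)
        old = replace(params.settings, horizon=20, start_age=70)
        t_young = b.run_cohort_trace(params.bd1, params.mortality, None,
                                     lifetable, young)
        t_old = b.run_cohort_trace(params.bd1, params.mortality, None,
                                   lifetable, old)
        # same per-cycle component table except productivity is zeroed for the
        # older cohort, so the healthcare totals move less than the societal
        d_soc_young, _ = arm_cost_totals(t_young, params.costs, None, "control",
                                         young, "societal")
        d_hc_young, _ = arm_cost_totals(t_young, params.costs, None, "control",
                                        young, "healthcare")
        d_soc_old, _ = arm_cost_totals(t_old, params.costs, None, "control",
                                       old, "societal")
        d_hc_old, _ = arm_cost_totals(t_old, params.costs, None, "control",
                                      old, "healthcare")
        assert d_soc_young - d_hc_young > 0  # productivity priced in below 67
        assert d_soc_old - d_hc_old < d_soc_young - d_hc_young


def _arm(costs_soc, qalys):
    costs = {"healthcare": costs_soc * 0.4, "societal": costs_soc}
    return ArmOutcomes(life_years=20.0, qalys=qalys, costs=costs,
                       life_years_undiscounted=25.0,
                       qalys_undiscounted=qalys * 1.2,
                       costs_undiscounted={k: v * 1.3 for k, v in costs.items()})


class TestIncrementalResults:
    @pytest.mark.parametrize("dc, dq, label, icer", [
        (-500.0, 0.018, "dominant", None),
        (100.0, 0.010, "icer", 10_000.0),
        (1.0, -0.010, "dominated", None),
        (-100.0, -0.010, "icer", 10_000.0),  # cheaper but worse: SW quadrant
    ])
    def test_classification(self, dc, dq, label, icer):
        control = _arm(100_000.0, 12.0)
        interv = _arm(100_000.0 + dc, 12.0 + dq)
        res = b.incremental_results(interv, control, "societal")
        assert res.label == label
        assert res.delta_costs == pytest.approx(dc)
        if icer is None:
            assert res.icer is None
        else:
            assert res.icer == pytest.approx(icer)

    def test_zero_qaly_difference_reports_no_icer(self):
        res = b.incremental_results(_arm(99_000.0, 12.0), _arm(100_000.0, 12.0),
                                    "societal")
        assert res.label == "no-qaly-difference"
        assert res.icer is None
        assert res.delta_costs == pytest.approx(-1_000.0)

    def test_nmb_at_wtp(self):
        res = b.incremental_results(_arm(100_100.0, 12.01), _arm(100_000.0, 12.0),
                                    "societal", wtp=50_000.0)
        assert res.nmb == pytest.approx(50_000 * 0.01 - 100.0)


class TestWeightedICER:
    def test_identical_subtypes_keep_icer(self):
        r = b.incremental_results(_arm(100_100.0, 12.01), _arm(100_000.0, 12.0),
                                  "societal")
        w = b.weighted_icer([r, r], [0.6, 0.4])
        assert w.icer == pytest.approx(r.icer)

    def test_degenerate_weights_recover_single_subtype(self):
        r1 = b.incremental_results(_arm(100_200.0, 12.02), _arm(100_000.0, 12.0),
                                   "societal")
        r2 = b.incremental_results(_arm(99_000.0, 11.99), _arm(100_000.0, 12.0),
                                   "societal")
        w = b.weighted_icer([r1, r2], [1.0, 0.0])
        assert w.delta_costs == pytest.approx(r1.delta_costs)
        assert w.delta_qalys == pytest.approx(r1.delta_qalys)
        assert w.icer == pytest.approx(r1.icer)

    def test_paper_style_weighted_dominance(self):
        r1 = b.incremental_results(_arm(100_000.0 - 400.0, 12.019),
                                   _arm(100_000.0, 12.0), "societal")
        r2 = b.incremental_results(_arm(100_000.0 - 600.0, 12.017),
                                   _arm(100_000.0, 12.0), "societal")
        w = b.weighted_icer([r1, r2], [0.6, 0.4])
        assert w.delta_costs == pytest.approx(-480.0)
        assert w.delta_qalys == pytest.approx(0.0182)
        assert w.label == "dominant"

    def test_ratio_of_weighted_increments_not_average_of_ratios(self):
        # counterexample where the two aggregations disagree
        r1 = b.incremental_results(_arm(100_100.0, 12.001), _arm(100_000.0, 12.0),
                                   "societal")  # ICER 100,000
        r2 = b.incremental_results(_arm(100_100.0, 12.1), _arm(100_000.0, 12.0),
                                   "societal")  # ICER 1,000
        w = b.weighted_icer([r1, r2], [0.5, 0.5])
        ratio_of_means = (0.5 * 100 + 0.5 * 100) / (0.5 * 0.001 + 0.5 * 0.1)
        mean_of_ratios = 0.5 * r1.icer + 0.5 * r2.icer
        assert w.icer == pytest.approx(ratio_of_means)
        assert abs(w.icer - mean_of_ratios) > 1_000

    def test_bad_weights_rejected(self):
        r = b.incremental_results(_arm(1.0, 12.01), _arm(0.0, 12.0), "societal")
        with pytest.raises(ValueError):
            b.weighted_icer([r, r], [0.7, 0.7])


class TestEvaluate:
    def test_null_intervention_increments_exactly_zero(self, short_params, lifetable):
        nulled = replace(short_params, intervention=b.InterventionSpec.null())
        res = b.evaluate(nulled, lifetable)
        for key in ("BD-I", "BD-II", "weighted"):
            assert res[key].delta_costs == 0.0
            assert res[key].delta_qalys == 0.0

    def test_weighted_equals_prevalence_combination(self, short_params, lifetable):
        res = b.evaluate(short_params, lifetable)
        dc = 0.6 * res["BD-I"].delta_costs + 0.4 * res["BD-II"].delta_costs
        dq = 0.6 * res["BD-I"].delta_qalys + 0.4 * res["BD-II"].delta_qalys
        assert res["weighted"].delta_costs == pytest.approx(dc, abs=1e-9)
        assert res["weighted"].delta_qalys == pytest.approx(dq, abs=1e-12)

    def test_default_intervention_gains_qalys(self, params, lifetable):
        res = b.evaluate(params, lifetable)
        for key in ("BD-I", "BD-II", "weighted"):
            assert res[key].delta_qalys > 0


class TestScenarioAnalysis:
    def test_base_ratio_split_values(self, params):
        from bipolarce.economics import _resplit_subtype

        re1 = _resplit_subtype(params.bd1, 4.7)
        assert re1.remission_row[1] == pytest.approx(0.0989, abs=5e-5)
        assert re1.remission_row[2] == pytest.approx(0.0211, abs=5e-5)
        re6 = _resplit_subtype(params.bd1, 6.0)
        assert re6.remission_row[1] == pytest.approx(0.1029, abs=5e-5)
        assert re6.remission_row[2] == pytest.approx(0.0171, abs=5e-5)
        # total exit preserved exactly
        assert sum(re6.remission_row[1:]) == pytest.approx(0.120, abs=1e-12)

    def test_extreme_ratio_limit(self, params):
        from bipolarce.economics import _resplit_subtype

        extreme = _resplit_subtype(params.bd1, 1e9)
        assert extreme.remission_row[2] == pytest.approx(0.0, abs=1e-9)

    def test_scenario_table_layout(self, short_params, lifetable):
        df = b.scenario_ratio_analysis(short_params, lifetable,
                                       [(6.0, 14.0), (3.6, 38.7)])
        assert list(df["scenario"]) == ["base", "ratios 6/14", "ratios 3.6/38.7"]
        assert {"delta_costs", "delta_qalys", "label", "icer"} <= set(df.columns)
        assert df.loc[0, "ratio_bd1"] == 4.7 and df.loc[0, "ratio_bd2"] == 10.7
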