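"""Economic valuation and cost-effectiveness results.

Values cohort traces in 2021 euros under the healthcare or societal
perspective, forms per-arm totals, incremental results and the ICER (with
dominance labelling), combines the two subtypes into a prevalence-weighted
result, and runs the depression/mania-ratio scenario analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .derivation import split_relapse_probability
from .engine import (
    CohortTrace,
    accumulate_outcomes,
    discount_factors,
    effective_occupancy,
    run_cohort_trace,
)
from .lifetable import LifeTable
from .parameters import (
    ALIVE_STATES,
    CostTable,
    HealthState,
    InterventionSpec,
    ModelSettings,
    ParameterSet,
    SubtypeParameters,
    perspective_components,
)

__all__ = ["ArmOutcomes", "CEResult", "state_cycle_cost", "arm_cost_totals",
           "evaluate_arm", "incremental_results", "weighted_icer",
           "evaluate", "scenario_ratio_analysis", "PERSPECTIVES"]

PERSPECTIVES = ("healthcare", "societal")


@dataclass(frozen=True)
class ArmOutcomes:
    """Totals for one arm: life years, QALYs, and costs per perspective."""

    life_years: float
    qalys: float
    costs: dict[str, float]  # perspective -> discounted total EUR
    life_years_undiscounted: float
    qalys_undiscounted: float
    costs_undiscounted: dict[str, float]

    @staticmethod
    def weighted(outcomes: list["ArmOutcomes"], weights: list[float]) -> "ArmOutcomes":
        def wsum(getter):
            return sum(w * getter(o) for o, w in zip(outcomes, weights))

        return ArmOutcomes(
            life_years=wsum(lambda o: o.life_years),
            qalys=wsum(lambda o: o.qalys),
            costs={p: wsum(lambda o: o.costs[p]) for p in PERSPECTIVES},
            life_years_undiscounted=wsum(lambda o: o.life_years_undiscounted),
            qalys_undiscounted=wsum(lambda o: o.qalys_undiscounted),
            costs_undiscounted={p: wsum(lambda o: o.costs_undiscounted[p])
                                for p in PERSPECTIVES},
        )


def state_cycle_cost(
    state: HealthState,
    age: int,
    arm: str,
    cycle_index: int,
    cost_table: CostTable,
    intervention: InterventionSpec | None,
    perspective: str,
) -> float:
    """Per-cycle cost of occupying a state, in EUR.

    Sums the state's cost components included in the perspective, zeroing
    productivity losses from the retirement age onwards, and adds the
    intervention's per-cycle cost in the intervention arm while its cost
    window lasts (optionally restricted to remission).
    """
    if state is HealthState.DEATH:
        return 0.0
    include_productivity = age < cost_table.retirement_age
    total = cost_table.state_total(state, perspective, include_productivity)
    if (
        intervention is not None
        and arm == "intervention"
        and cycle_index < intervention.cost_cycles
        and (intervention.cost_states == "alive" or state is HealthState.REMISSION)
    ):
        total += intervention.cost_per_cycle
    return total


def _cost_matrix(
    trace: CohortTrace,
    cost_table: CostTable,
    intervention: InterventionSpec | None,
    arm: str,
    perspective: str,
) -> np.ndarray:
    """(n_cycles, 3) per-cycle cost of each alive state."""
    n = trace.n_cycles
    out = np.empty((n, 3))
    for t in range(n):
        age = int(trace.ages[t])
        for j, state in enumerate(ALIVE_STATES):
            out[t, j] = state_cycle_cost(
                state, age, arm, t, cost_table, intervention, perspective
            )
    return out


def arm_cost_totals(
    trace: CohortTrace,
    cost_table: CostTable,
    intervention: InterventionSpec | None,
    arm: str,
    settings: ModelSettings,
    perspective: str,
) -> tuple[float, float]:
    """(discounted, undiscounted) total cost for one arm's trace.

    Uses the same half-cycle-corrected occupancy as the health outcomes and
    the cost discount rate.
    """
    eff = effective_occupancy(trace, settings.half_cycle_correction)[:, :3]
    costs = _cost_matrix(trace, cost_table, intervention, arm, perspective)
    per_cycle = (eff * costs).sum(axis=1)
    df = discount_factors(trace.n_cycles, settings.discount_rate_costs,
                          trace.cycle_length_years)
    return float(per_cycle @ df), float(per_cycle.sum())


def evaluate_arm(
    subtype: SubtypeParameters,
    params: ParameterSet,
    arm: str,
    lifetable: LifeTable,
) -> ArmOutcomes:
    """Run one subtype/arm trace and value it under both perspectives."""
    intervention = params.intervention if arm == "intervention" else None
    trace = run_cohort_trace(subtype, params.mortality, intervention,
                             lifetable, params.settings)
    health = accumulate_outcomes(trace, subtype.utilities, params.settings)
    costs, costs_undisc = {}, {}
    for perspective in PERSPECTIVES:
        d, u = arm_cost_totals(trace, params.costs, intervention, arm,
                               params.settings, perspective)
        costs[perspective] = d
        costs_undisc[perspective] = u
    return ArmOutcomes(
        life_years=health["life_years"],
        qalys=health["qalys"],
        costs=costs,
        life_years_undiscounted=health["life_years_undiscounted"],
        qalys_undiscounted=health["qalys_undiscounted"],
        costs_undiscounted=costs_undisc,
    )


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness result for one comparison.

    The ICER (delta cost / delta QALYs on discounted totals) is reported
    only when it is informative: a cheaper-and-more-effective intervention
    is 'dominant', a costlier-and-less-effective one 'dominated', and a
    zero QALY difference yields no ratio.
    """

    control: ArmOutcomes | None
    intervention: ArmOutcomes | None
    delta_costs: float
    delta_qalys: float
    delta_life_years: float
    label: str  # 'dominant' | 'dominated' | 'icer' | 'no-qaly-difference'
    icer: float | None
    nmb: float | None = None  # net monetary benefit at the supplied WTP

    def summary(self) -> dict:
        return {
            "delta_costs": self.delta_costs,
            "delta_qalys": self.delta_qalys,
            "delta_life_years": self.delta_life_years,
            "label": self.label,
            "icer": self.icer,
            "nmb": self.nmb,
        }


def _classify(delta_costs: float, delta_qalys: float) -> tuple[str, float | None]:
    if delta_qalys == 0.0:
        return "no-qaly-difference", None
    if delta_qalys > 0 and delta_costs < 0:
        return "dominant", None
    if delta_qalys < 0 and delta_costs > 0:
        return "dominated", None
    return "icer", delta_costs / delta_qalys


def incremental_results(
    intervention: ArmOutcomes,
    control: ArmOutcomes,
    perspective: str,
    wtp: float | None = None,
) -> CEResult:
    """Incremental costs, QALYs, and ICER/dominance for one comparison."""
    perspective_components(perspective)
    dc = intervention.costs[perspective] - control.costs[perspective]
    dq = intervention.qalys - control.qalys
    dly = intervention.life_years - control.life_years
    label, icer = _classify(dc, dq)
    nmb = (wtp * dq - dc) if wtp is not None else None
    return CEResult(control=control, intervention=intervention,
                    delta_costs=dc, delta_qalys=dq, delta_life_years=dly,
                    label=label, icer=icer, nmb=nmb)


def weighted_icer(
    results: list[CEResult],
    weights: list[float],
    wtp: float | None = None,
) -> CEResult:
    """Prevalence-weighted result across subtypes.

    Increments (delta costs, delta QALYs) are weighted first and the ratio
    formed afterwards — the weighted ICER is a ratio of weighted increments,
    not a weighted average of per-subtype ICERs.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    dc = sum(w * r.delta_costs for r, w in zip(results, weights))
    dq = sum(w * r.delta_qalys for r, w in zip(results, weights))
    dly = sum(w * r.delta_life_years for r, w in zip(results, weights))
    control = intervention = None
    if all(r.control is not None for r in results):
        control = ArmOutcomes.weighted([r.control for r in results], weights)
    if all(r.intervention is not None for r in results):
        intervention = ArmOutcomes.weighted([r.intervention for r in results], weights)
    label, icer = _classify(dc, dq)
    nmb = (wtp * dq - dc) if wtp is not None else None
    return CEResult(control=control, intervention=intervention,
                    delta_costs=dc, delta_qalys=dq, delta_life_years=dly,
                    label=label, icer=icer, nmb=nmb)


def evaluate(
    params: ParameterSet,
    lifetable: LifeTable,
    perspective: str | None = None,
    wtp: float | None = None,
) -> dict[str, CEResult]:
    """Full deterministic analysis: per-subtype and prevalence-weighted.

    Returns a mapping with keys 'BD-I', 'BD-II', and 'weighted'.
    """
    perspective = perspective or params.settings.perspective
    per_subtype: list[CEResult] = []
    out: dict[str, CEResult] = {}
    for subtype in params.subtypes:
        control = evaluate_arm(subtype, params, "control", lifetable)
        interv = evaluate_arm(subtype, params, "intervention", lifetable)
        res = incremental_results(interv, control, perspective, wtp)
        per_subtype.append(res)
        out[subtype.subtype] = res
    weights = [s.prevalence_weight for s in params.subtypes]
    out["weighted"] = weighted_icer(per_subtype, weights, wtp)
    return out


def _resplit_subtype(subtype: SubtypeParameters, ratio: float) -> SubtypeParameters:
    """Re-split the subtype's total remission-exit probability by a new ratio.

    The total probability of leaving remission per cycle is held at its
    default value; only its allocation between depression and (hypo)mania
    changes with the scenario's depression/mania time ratio.
    """
    total_exit = subtype.remission_row[1] + subtype.remission_row[2]
    p_dep, p_epi = split_relapse_probability(total_exit, ratio)
    return replace(
        subtype,
        remission_row=(1.0 - total_exit, p_dep, p_epi),
        depression_mania_ratio=ratio,
    )


def scenario_ratio_analysis(
    params: ParameterSet,
    lifetable: LifeTable,
    ratio_pairs: list[tuple[float, float]],
    perspective: str | None = None,
) -> pd.DataFrame:
    """One-way scenario analysis over depression/mania time ratios.

    Each scenario re-splits both subtypes' remission-exit probabilities by
    the supplied (BD-I, BD-II) ratio pair, reruns both arms, and reports the
    weighted incremental results next to the base case.
    """
    rows = []

    def record(name: str, p: ParameterSet, r1: float, r2: float):
        res = evaluate(p, lifetable, perspective)
        w = res["weighted"]
        rows.append({
            "scenario": name,
            "ratio_bd1": r1,
            "ratio_bd2": r2,
            "remission_row_bd1": tuple(round(x, 6) for x in p.bd1.remission_row),
            "remission_row_bd2": tuple(round(x, 6) for x in p.bd2.remission_row),
            "delta_costs": w.delta_costs,
            "delta_qalys": w.delta_qalys,
            "label": w.label,
            "icer": w.icer,
        })

    record("base", params, params.bd1.depression_mania_ratio,
           params.bd2.depression_mania_ratio)
    for r1, r2 in ratio_pairs:
        scenario = replace(
            params,
            bd1=_resplit_subtype(params.bd1, r1),
            bd2=_resplit_subtype(params.bd2, r2),
        )
        record(f"ratios {r1:g}/{r2:g}", scenario, r1, r2)
    return pd.DataFrame(rows)
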