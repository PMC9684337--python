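"""Probabilistic sensitivity analysis.

Second-order uncertainty is propagated by sampling a full parameter set per
iteration — Dirichlet transition rows, beta utilities, gamma costs,
lognormal rate ratios, beta-PERT for bounded quantities — rerunning both
arms for both subtypes, and summarising the cloud of prevalence-weighted
incremental (cost, QALY) pairs as a cost-effectiveness plane and a CEAC
under the net-monetary-benefit rule.

Draw order within an iteration is fixed by spawning one independent child
random stream per parameter block (transitions, utilities, costs, rate
ratios), so adding a parameter to one block never reshuffles the draws of
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import evaluate
from .lifetable import LifeTable
from .parameters import (
    COST_COMPONENTS,
    ParameterSet,
    ParameterValidationError,
    SubtypeParameters,
    UncertaintySpec,
)

__all__ = ["PSAResult", "sample_parameter_set", "run_psa", "ceac",
           "beta_pert", "beta_from_mean_se", "gamma_from_mean_cv",
           "lognormal_ratio"]


def beta_from_mean_se(mean: float, se: float, rng: np.random.Generator) -> float:
    """Beta draw matched to a mean in (0, 1) and a standard error.

    ``se = 0`` degenerates to the mean; a negative dispersion is an error.
    The requested variance is capped just below the Bernoulli bound
    mean*(1-mean) so the method-of-moments shape parameters stay positive.
    """
    if se < 0:
        raise ParameterValidationError(f"utility SE must be >= 0, got {se}")
    if se == 0 or mean in (0.0, 1.0):
        return mean
    if not 0.0 < mean < 1.0:
        raise ParameterValidationError(f"beta mean must be in (0, 1), got {mean}")
    var = min(se * se, 0.999 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def gamma_from_mean_cv(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Gamma draw matched to a mean and coefficient of variation."""
    if cv < 0:
        raise ParameterValidationError(f"cost CV must be >= 0, got {cv}")
    if cv == 0 or mean == 0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def lognormal_ratio(mean: float, log_sd: float, rng: np.random.Generator) -> float:
    """Median-preserving lognormal draw for a rate/relative risk."""
    if log_sd < 0:
        raise ParameterValidationError(f"log-SD must be >= 0, got {log_sd}")
    if log_sd == 0:
        return mean
    return float(rng.lognormal(math.log(mean), log_sd))


def beta_pert(minimum: float, mode: float, maximum: float,
              rng: np.random.Generator, shape: float = 4.0) -> float:
    """Beta-PERT draw on [minimum, maximum] with the given mode.

    Standard PERT parameterization: alpha = 1 + shape*(mode-min)/(max-min),
    beta = 1 + shape*(max-mode)/(max-min).  A zero-width interval
    degenerates to the common point.
    """
    if not minimum <= mode <= maximum:
        raise ParameterValidationError(
            f"beta-PERT requires min <= mode <= max, got {(minimum, mode, maximum)}"
        )
    width = maximum - minimum
    if width == 0:
        return minimum
    a = 1.0 + shape * (mode - minimum) / width
    b = 1.0 + shape * (maximum - mode) / width
    return minimum + width * float(rng.beta(a, b))


def _sample_row(row: tuple[float, ...], ess: float,
                rng: np.random.Generator) -> tuple[float, ...]:
    """Dirichlet draw around a mean transition row (ess = inf pins it)."""
    if math.isinf(ess):
        return row
    mean = np.asarray(row)
    positive = mean > 0
    draw = np.array(mean, dtype=float)
    # zero-probability transitions stay structurally impossible
    draw[positive] = rng.dirichlet(mean[positive] * ess)
    return tuple(draw)


def _sample_subtype(sub: SubtypeParameters, unc: UncertaintySpec,
                    rng: np.random.Generator) -> dict:
    return {
        "remission_row": _sample_row(sub.remission_row, unc.transition_ess, rng),
        "depression_row": _sample_row(sub.depression_row, unc.transition_ess, rng),
        "episode_row": _sample_row(sub.episode_row, unc.transition_ess, rng),
    }


def sample_parameter_set(base: ParameterSet, unc: UncertaintySpec,
                         seed_seq: np.random.SeedSequence) -> ParameterSet:
    """Draw one parameter set around the base values.

    Transition rows are Dirichlet (concentration = mean row x effective
    sample size), utilities beta, per-state per-component costs gamma, and
    the mortality and intervention rate ratios lognormal.  Zero dispersion
    (or an infinite effective sample size) pins the corresponding block to
    its base values, so a fully degenerate configuration reproduces the
    deterministic analysis draw for draw.
    """
    rng_trans, rng_util, rng_cost, rng_rr = (
        np.random.default_rng(s) for s in seed_seq.spawn(4)
    )

    new_subs = []
    for sub in (base.bd1, base.bd2):
        rows = _sample_subtype(sub, unc, rng_trans)
        new_subs.append(replace(
            sub,
            **rows,
            utility_remission=beta_from_mean_se(sub.utility_remission,
                                                unc.utility_se, rng_util),
            utility_depression=beta_from_mean_se(sub.utility_depression,
                                                 unc.utility_se, rng_util),
            utility_episode=beta_from_mean_se(sub.utility_episode,
                                              unc.utility_se, rng_util),
        ))

    per_state = {
        state: {
            comp: gamma_from_mean_cv(base.costs.per_state[state].get(comp, 0.0),
                                     unc.cost_cv, rng_cost)
            for comp in COST_COMPONENTS
        }
        for state in base.costs.per_state
    }
    costs = replace(base.costs, per_state=per_state)

    mortality = replace(
        base.mortality,
        mrr_all_states=lognormal_ratio(base.mortality.mrr_all_states,
                                       unc.rr_log_sd, rng_rr),
        mrr_suicide_depression=lognormal_ratio(base.mortality.mrr_suicide_depression,
                                               unc.rr_log_sd, rng_rr),
    )
    intervention = replace(
        base.intervention,
        rr_depression=lognormal_ratio(base.intervention.rr_depression,
                                      unc.rr_log_sd, rng_rr),
        rr_episode=lognormal_ratio(base.intervention.rr_episode,
                                   unc.rr_log_sd, rng_rr),
        cost_per_cycle=gamma_from_mean_cv(base.intervention.cost_per_cycle,
                                          unc.cost_cv, rng_cost),
    )

    return replace(base, bd1=new_subs[0], bd2=new_subs[1], costs=costs,
                   mortality=mortality, intervention=intervention)


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo cloud of prevalence-weighted incremental outcomes."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    n_iterations: int
    seed: int
    perspective: str

    def __post_init__(self):
        if len(self.delta_costs) != self.n_iterations:
            raise ValueError("pair count must equal the iteration count")

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_qaly": self.delta_qalys,
            "delta_cost": self.delta_costs,
        })

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        nmb = wtp * self.delta_qalys - self.delta_costs
        return float(np.mean(nmb > 0))


def run_psa(
    params: ParameterSet,
    lifetable: LifeTable,
    n_iterations: int | None = None,
    seed: int | None = None,
    perspective: str | None = None,
) -> PSAResult:
    """Run the probabilistic sensitivity analysis.

    Deterministic given the seed: iteration i always receives the i-th
    spawn of the root seed sequence regardless of how many iterations are
    requested.
    """
    n = n_iterations if n_iterations is not None else params.settings.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    seed = seed if seed is not None else params.settings.seed
    perspective = perspective or params.settings.perspective
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        sampled = sample_parameter_set(params, params.uncertainty, children[i])
        result = evaluate(sampled, lifetable, perspective)["weighted"]
        dc[i] = result.delta_costs
        dq[i] = result.delta_qalys
    return PSAResult(delta_costs=dc, delta_qalys=dq, n_iterations=n,
                     seed=seed, perspective=perspective)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve on a WTP grid.

    At each threshold the probability is the fraction of iterations with
    strictly positive net monetary benefit (ties count as not
    cost-effective).
    """
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("WTP grid must be non-empty")
    return pd.DataFrame({
        "wtp": grid,
        "probability_cost_effective": [
            psa.probability_cost_effective(wtp) for wtp in grid
        ],
    })
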