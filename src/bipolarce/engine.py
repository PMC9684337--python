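"""Markov cohort engine.

Advances the per-cycle state-occupancy trace for one subtype and arm:
builds the 3x3 alive-state matrix (with the intervention's relative risks
while its effect lasts), embeds age-specific background mortality as a
competing risk, and accumulates life years and QALYs with half-cycle
correction and annual discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .derivation import (
    apply_intervention_effect,
    build_transition_matrix,
    state_death_probability,
)
from .lifetable import LifeTable
from .parameters import (
    ALIVE_STATES,
    HealthState,
    InterventionSpec,
    ModelSettings,
    MortalityParameters,
    SubtypeParameters,
)

__all__ = ["CohortTrace", "EngineError", "embed_mortality", "steady_state",
           "run_cohort_trace", "accumulate_outcomes", "effective_occupancy",
           "discount_factors"]

#: Column order of every 4-state occupancy array.
STATE_ORDER = (HealthState.REMISSION, HealthState.DEPRESSION,
               HealthState.EPISODE, HealthState.DEATH)


class EngineError(ValueError):
    """Raised for degenerate engine inputs."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy over (remission, depression, episode, death).

    ``occupancy`` has shape (n_cycles + 1, 4): row t is the distribution at
    the start of cycle t, the final row the distribution after the last
    cycle.  ``ages`` gives the integer cohort age at each cycle boundary.
    """

    occupancy: np.ndarray
    ages: np.ndarray
    cycle_length_years: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy,
                          columns=[s.value for s in STATE_ORDER])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def embed_mortality(alive_row: np.ndarray, death_prob: float) -> np.ndarray:
    """Expand one alive-state row to 4 states given its death probability.

    Death competes proportionally: the death entry is ``death_prob`` and
    every alive destination is scaled by ``1 - death_prob``.
    """
    if not 0.0 <= death_prob <= 1.0:
        raise EngineError(f"death probability must be in [0, 1], got {death_prob}")
    row = np.asarray(alive_row, dtype=float)
    out = np.empty(4)
    out[:3] = row * (1.0 - death_prob)
    out[3] = death_prob
    return out


def _embed_matrix(alive: np.ndarray, death_probs: np.ndarray) -> np.ndarray:
    """4x4 cycle matrix from a 3x3 alive matrix and per-origin death probs."""
    full = np.zeros((4, 4))
    full[:3, :3] = alive * (1.0 - death_probs)[:, None]
    full[:3, 3] = death_probs
    full[3, 3] = 1.0
    return full


def steady_state(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Solves pi P = pi with sum(pi) = 1 by least squares and verifies the
    solution; used for the epidemiology validation against observed
    mood-state prevalences.
    """
    P = np.asarray(matrix, dtype=float)
    n = P.shape[0]
    if P.shape != (n, n):
        raise EngineError("matrix must be square")
    if np.linalg.matrix_rank(P.T - np.eye(n)) != n - 1:
        raise EngineError("no unique stationary distribution (reducible chain)")
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-9) or not np.allclose(pi @ P, pi, atol=1e-9):
        raise EngineError("no unique stationary distribution (reducible or degenerate chain)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _n_cycles(settings: ModelSettings, lifetable: LifeTable) -> int:
    if settings.horizon == "lifetime":
        span = lifetable.terminal_age - settings.start_age
        if span <= 0:
            raise EngineError(
                f"start age {settings.start_age} is at or beyond the lifetable "
                f"terminal age {lifetable.terminal_age}"
            )
        return math.ceil(span / settings.cycle_length_years)
    return int(settings.horizon)


def run_cohort_trace(
    subtype: SubtypeParameters,
    mortality: MortalityParameters,
    intervention: InterventionSpec | None,
    lifetable: LifeTable,
    settings: ModelSettings,
) -> CohortTrace:
    """Run the cohort trace for one subtype and one arm.

    The intervention's relative risks modify the alive-state matrix for the
    first ``effect_cycles`` cycles; afterwards (and in the control arm,
    ``intervention=None``) the standard-of-care matrix applies.  Mortality
    is embedded per cycle using the annual death probability at the
    cohort's integer age at cycle start.
    """
    base = build_transition_matrix(subtype)
    effective = (apply_intervention_effect(base, intervention)
                 if intervention is not None else base)
    n = _n_cycles(settings, lifetable)
    if n < 1:
        raise EngineError("horizon must cover at least one cycle")

    occ = np.zeros((n + 1, 4))
    occ[0, :3] = settings.start_distribution
    ages = np.array([
        int(math.floor(settings.start_age + t * settings.cycle_length_years))
        for t in range(n + 1)
    ])

    cache: dict[tuple[int, bool], np.ndarray] = {}
    for t in range(n):
        use_effect = intervention is not None and t < intervention.effect_cycles
        key = (ages[t], use_effect)
        M = cache.get(key)
        if M is None:
            q = lifetable.annual_q(ages[t])
            deaths = np.array([
                state_death_probability(q, s, mortality, settings.cycle_length_years)
                for s in ALIVE_STATES
            ])
            M = _embed_matrix(effective if use_effect else base, deaths)
            cache[key] = M
        occ[t + 1] = occ[t] @ M
    return CohortTrace(occupancy=occ, ages=ages,
                       cycle_length_years=settings.cycle_length_years)


def effective_occupancy(trace: CohortTrace, half_cycle_correction: bool) -> np.ndarray:
    """Per-cycle occupancy credited for outcome accumulation.

    With half-cycle correction the trapezoid (mean of cycle start and end)
    is used, crediting transitions as if they occur mid-cycle; otherwise
    the cycle-start occupancy.
    """
    occ = trace.occupancy
    if half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def discount_factors(n_cycles: int, annual_rate: float, cycle_length_years: float) -> np.ndarray:
    """Per-cycle discount factors (1 + r)^(-t * cycle length); cycle 0 is 1."""
    t = np.arange(n_cycles) * cycle_length_years
    return (1.0 + annual_rate) ** (-t)


def accumulate_outcomes(
    trace: CohortTrace,
    utilities: dict[HealthState, float],
    settings: ModelSettings,
) -> dict[str, float]:
    """Life years and QALYs from a trace, discounted and undiscounted."""
    eff = effective_occupancy(trace, settings.half_cycle_correction)
    cyc = trace.cycle_length_years
    u = np.array([utilities[s] for s in ALIVE_STATES])
    ly_per_cycle = eff[:, :3].sum(axis=1) * cyc
    qaly_per_cycle = eff[:, :3] @ u * cyc
    df = discount_factors(trace.n_cycles, settings.discount_rate_effects, cyc)
    return {
        "life_years": float(ly_per_cycle @ df),
        "qalys": float(qaly_per_cycle @ df),
        "life_years_undiscounted": float(ly_per_cycle.sum()),
        "qalys_undiscounted": float(qaly_per_cycle.sum()),
    }
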