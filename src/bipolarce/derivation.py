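"""Probability calculus turning published evidence into cycle-level inputs.

All period conversions assume a constant hazard within the source period,
so a probability ``p`` over one period becomes ``1 - (1 - p)**f`` over a
period ``f`` times as long.  Episode durations are modeled as exponential
time-to-recovery fitted to published survival quantiles, and excess
mortality enters as rate ratios on the background death rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .parameters import (
    ALIVE_STATES,
    HealthState,
    InterventionSpec,
    MortalityParameters,
    ParameterValidationError,
    SubtypeParameters,
)

__all__ = [
    "SurvivalQuantile",
    "AnnualRecurrence",
    "DerivationError",
    "convert_probability_period",
    "relative_risk_from_recurrence",
    "split_relapse_probability",
    "fit_exponential_recovery",
    "survival_probability",
    "build_transition_matrix",
    "apply_intervention_effect",
    "state_death_probability",
]


class DerivationError(ValueError):
    """Raised for infeasible or out-of-domain derivation inputs."""


@dataclass(frozen=True)
class SurvivalQuantile:
    """A (time, surviving fraction) point on an episode-duration curve."""

    weeks: float
    surviving: float

    def __post_init__(self):
        if not (self.weeks > 0 and math.isfinite(self.weeks)):
            raise DerivationError(f"time must be finite and > 0, got {self.weeks}")
        if not 0.0 < self.surviving < 1.0:
            raise DerivationError(f"surviving fraction must be in (0, 1), got {self.surviving}")


@dataclass(frozen=True)
class AnnualRecurrence:
    """A 12-month recurrence probability for one trial arm."""

    probability: float
    arm: str = ""

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise DerivationError(f"probability must be in [0, 1], got {self.probability}")


def convert_probability_period(p: float, fraction: float) -> float:
    """Rescale a probability to a period ``fraction`` times as long.

    Under a constant hazard, ``1 - (1 - p)**fraction``; e.g. an annual
    recurrence of 21.9% becomes a quarterly probability of 5.99%
    (fraction 0.25).  Inverse conversion via ``fraction = 1/f``.
    """
    if not 0.0 <= p <= 1.0:
        raise DerivationError(f"probability must be in [0, 1], got {p}")
    if fraction <= 0:
        raise DerivationError(f"period fraction must be > 0, got {fraction}")
    if p == 1.0:
        return 1.0
    # log1p/expm1 keep the round trip exact to ~1e-15 even for extreme fractions
    return -math.expm1(fraction * math.log1p(-p))


def relative_risk_from_recurrence(
    p_control_annual: float, p_intervention_annual: float, fraction: float = 0.25
) -> float:
    """Cycle-scale relative risk from two annual recurrence probabilities.

    Both arms are rescaled to the cycle period first, then the ratio of
    intervention over control is taken.
    """
    if not 0.0 < p_control_annual < 1.0:
        raise DerivationError(
            f"control recurrence must be in (0, 1), got {p_control_annual}"
        )
    if not 0.0 < p_intervention_annual < 1.0:
        raise DerivationError(
            f"intervention recurrence must be in (0, 1), got {p_intervention_annual}"
        )
    return convert_probability_period(p_intervention_annual, fraction) / (
        convert_probability_period(p_control_annual, fraction)
    )


def split_relapse_probability(p_total: float, ratio: float) -> tuple[float, float]:
    """Split a total relapse probability into depression and episode parts.

    ``ratio`` is the depression/mania time ratio; the split is proportional,
    and the two parts sum to ``p_total`` exactly.
    """
    if not 0.0 <= p_total <= 1.0:
        raise DerivationError(f"total probability must be in [0, 1], got {p_total}")
    if ratio <= 0:
        raise DerivationError(f"ratio must be > 0, got {ratio}")
    # compute the larger share directly and the smaller by subtraction: the
    # subtrahend is then >= p_total/2, so the subtraction is exact
    # (Sterbenz) and the two parts sum to p_total exactly in floating point
    if ratio >= 1.0:
        p_dep = p_total * ratio / (1.0 + ratio)
        p_epi = p_total - p_dep
    else:
        p_epi = p_total / (1.0 + ratio)
        p_dep = p_total - p_epi
    return p_dep, p_epi


def fit_exponential_recovery(points: Sequence[SurvivalQuantile | tuple]) -> float:
    """Weekly recovery rate from survival quantiles of episode duration.

    A single point gives the closed form ``-ln(S)/t``; several points are
    fitted by least squares of ``-ln(S)`` on ``t`` through the origin.
    """
    pts = [p if isinstance(p, SurvivalQuantile) else SurvivalQuantile(*p) for p in points]
    if not pts:
        raise DerivationError("at least one survival quantile is required")
    t = np.array([p.weeks for p in pts])
    y = -np.log([p.surviving for p in pts])
    return float(np.dot(t, y) / np.dot(t, t))


def survival_probability(rate_per_week: float, weeks: float) -> float:
    """Probability of remaining in an episode after ``weeks`` weeks."""
    if rate_per_week < 0 or weeks < 0:
        raise DerivationError("rate and time must be >= 0")
    return math.exp(-rate_per_week * weeks)


_ORIGINS = (HealthState.REMISSION, HealthState.DEPRESSION, HealthState.EPISODE)


def build_transition_matrix(subtype: SubtypeParameters) -> np.ndarray:
    """3x3 alive-state quarterly transition matrix for one subtype.

    Rows and columns are ordered (remission, depression, episode).  The
    residual entry of each row — remission's own diagonal, and the
    return-to-remission entry of the two mood-state rows — is recomputed as
    one minus the explicit exits, so the matrix is row-stochastic by
    construction.  In this ordering the residual is always column 0.
    """
    rows = {
        HealthState.REMISSION: subtype.remission_row,
        HealthState.DEPRESSION: subtype.depression_row,
        HealthState.EPISODE: subtype.episode_row,
    }
    out = np.empty((3, 3))
    for i, origin in enumerate(_ORIGINS):
        row = list(rows[origin])
        exits = row[1] + row[2]
        if exits > 1.0 + 1e-12:
            raise DerivationError(
                f"{subtype.subtype} {origin.value} row: exit probabilities sum to "
                f"{exits:.6g} > 1"
            )
        row[0] = 1.0 - exits
        out[i] = row
    return out


def apply_intervention_effect(matrix: np.ndarray, spec: InterventionSpec) -> np.ndarray:
    """Scale episode-entry probabilities by the intervention relative risks.

    Entries into depression (column 1) are multiplied by ``rr_depression``
    and entries into the (hypo)mania state (column 2) by ``rr_episode``.
    The default relapse-only scope touches only the remission row; the
    all-entries scope additionally scales the depression->episode and
    episode->depression switches (diagonals are never scaled).  Each
    modified row's residual — remission->remission, or the mood state's
    return to remission — is recomputed so the row still sums to 1.
    """
    out = np.array(matrix, dtype=float, copy=True)

    def rescale(i: int):
        to_dep = out[i, 1] if i == 1 else out[i, 1] * spec.rr_depression
        to_epi = out[i, 2] if i == 2 else out[i, 2] * spec.rr_episode
        occupied = to_dep + to_epi
        if occupied > 1.0 + 1e-12:
            origin = _ORIGINS[i].value
            raise DerivationError(
                f"intervention RRs make the {origin} row infeasible: "
                f"scaled exits sum to {occupied:.6g} > 1"
            )
        out[i, 1] = to_dep
        out[i, 2] = to_epi
        out[i, 0] = 1.0 - occupied

    rescale(0)  # remission row in every scope
    if spec.scope == "all-entries":
        rescale(1)  # depression row: switch into (hypo)mania
        rescale(2)  # episode row: switch into depression
    return out


def state_death_probability(
    q_annual: float,
    state: HealthState,
    mortality: MortalityParameters,
    cycle_length_years: float = 0.25,
) -> float:
    """Per-cycle death probability in a state given background mortality.

    The annual probability is converted to a rate, multiplied by the
    all-state mortality rate ratio, combined with the suicide ratio in the
    depression state (multiplicatively on the rate scale by default, or by
    adding excess rates), and converted back for the cycle length.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise DerivationError(f"annual death probability must be in [0, 1], got {q_annual}")
    if cycle_length_years <= 0:
        raise DerivationError("cycle length must be > 0")
    if state is HealthState.DEATH:
        return 1.0
    if q_annual >= 1.0:
        return 1.0
    rate = -math.log1p(-q_annual)
    multiplier = mortality.mrr_all_states
    if state is HealthState.DEPRESSION:
        if mortality.combination == "multiplicative":
            multiplier *= mortality.mrr_suicide_depression
        else:  # additive-on-rate: excess rates add on top of background
            multiplier += mortality.mrr_suicide_depression - 1.0
    return min(1.0, 1.0 - math.exp(-rate * multiplier * cycle_length_years))
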