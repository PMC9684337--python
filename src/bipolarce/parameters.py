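"""Parameter model for the bipolar-disorder cost-utility Markov model.

Holds the domain types (health states, subtype transition rows, mortality
rate ratios, per-cycle cost tables, intervention specifications, run
settings, PSA dispersions), the packaged default parameterization for
bipolar disorder types I and II, and strict config-file loading.

The default numbers describe a quarterly-cycle cohort model of the Dutch
standard of care: three alive mood states (remission, depression, and a
mood episode that is mania for BD-I and hypomania for BD-II) plus death,
standard-gamble utilities, 2021-euro per-cycle costs, and an add-on
relapse-prevention intervention (mindfulness-based cognitive therapy)
characterised by relative risks on episode entry.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "ROW_TOL",
    "COST_COMPONENTS",
    "HEALTHCARE_COMPONENTS",
    "SOCIETAL_COMPONENTS",
    "SubtypeParameters",
    "MortalityParameters",
    "CostTable",
    "IntensityMix",
    "InterventionSpec",
    "ModelSettings",
    "UncertaintySpec",
    "ParameterSet",
    "ConfigError",
    "ParameterValidationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "wtp_from_gdp",
    "DUTCH_GDP_PER_CAPITA_2021",
]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


class ParameterValidationError(ValueError):
    """Raised when a parameter value violates a model invariant."""


class HealthState(Enum):
    """The four Markov states; EPISODE is mania (BD-I) or hypomania (BD-II)."""

    REMISSION = "remission"
    DEPRESSION = "depression"
    EPISODE = "episode"
    DEATH = "death"


ALIVE_STATES = (HealthState.REMISSION, HealthState.DEPRESSION, HealthState.EPISODE)

#: Tolerance for transition-row stochasticity checks.
ROW_TOL = 1e-9

#: Cost components of the standard of care, per state per quarterly cycle.
COST_COMPONENTS = (
    "drugs",
    "medical_services",
    "psychological_treatment",
    "home_based_treatment",
    "indirect_medical",
    "productivity",
    "patient_family",
    "admission",
)

#: Components counted from the healthcare (payer) perspective.
HEALTHCARE_COMPONENTS = frozenset(
    c for c in COST_COMPONENTS if c not in ("productivity", "patient_family")
)
#: The societal perspective counts everything (healthcare is a strict subset).
SOCIETAL_COMPONENTS = frozenset(COST_COMPONENTS)

#: Dutch GDP per capita (2021, EUR), used for the WHO 3x-GDP WTP threshold.
DUTCH_GDP_PER_CAPITA_2021 = 49_100


def wtp_from_gdp(gdp_per_capita: float, multiplier: float = 3.0) -> float:
    """Willingness-to-pay threshold as a multiple of GDP per capita."""
    if gdp_per_capita < 0 or multiplier < 0:
        raise ParameterValidationError("GDP and multiplier must be nonnegative")
    return multiplier * gdp_per_capita


def _check_probability(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterValidationError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


def _check_row(name: str, row) -> tuple[float, float, float]:
    row = tuple(float(x) for x in row)
    if len(row) != 3:
        raise ParameterValidationError(f"{name} must have 3 entries, got {len(row)}")
    for x in row:
        _check_probability(f"{name} entry", x)
    if abs(sum(row) - 1.0) > ROW_TOL:
        raise ParameterValidationError(
            f"{name} must sum to 1 within {ROW_TOL:g}: {row} sums to {sum(row):.12g}"
        )
    return row


@dataclass(frozen=True)
class SubtypeParameters:
    """Disease-course parameters for one bipolar subtype.

    Transition rows are quarterly probabilities over the alive states in the
    order (to remission, to depression, to episode); each row describes the
    destinations of one origin state under the standard of care, before
    background mortality is embedded.
    """

    subtype: str
    prevalence_weight: float
    remission_row: tuple[float, float, float]
    depression_row: tuple[float, float, float]
    episode_row: tuple[float, float, float]
    depression_mania_ratio: float
    time_in_depression: float
    time_in_mania: float
    utility_remission: float
    utility_depression: float
    utility_episode: float

    def __post_init__(self):
        _check_probability("prevalence_weight", self.prevalence_weight)
        object.__setattr__(self, "remission_row", _check_row("remission_row", self.remission_row))
        object.__setattr__(self, "depression_row", _check_row("depression_row", self.depression_row))
        object.__setattr__(self, "episode_row", _check_row("episode_row", self.episode_row))
        if self.depression_mania_ratio <= 0:
            raise ParameterValidationError("depression_mania_ratio must be > 0")
        for name in ("time_in_depression", "time_in_mania", "utility_remission",
                     "utility_depression", "utility_episode"):
            _check_probability(name, getattr(self, name))

    @property
    def utilities(self) -> dict[HealthState, float]:
        return {
            HealthState.REMISSION: self.utility_remission,
            HealthState.DEPRESSION: self.utility_depression,
            HealthState.EPISODE: self.utility_episode,
            HealthState.DEATH: 0.0,
        }


@dataclass(frozen=True)
class MortalityParameters:
    """Excess-mortality rate ratios applied to background mortality.

    ``mrr_all_states`` captures comorbidity and lifestyle excess mortality in
    every alive state; ``mrr_suicide_depression`` is the additional suicide
    rate ratio applied in the depression state only.  The two are combined on
    the rate scale, multiplicatively by default.
    """

    mrr_all_states: float = 2.06
    mrr_suicide_depression: float = 9.66
    combination: str = "multiplicative"  # or "additive-on-rate"

    def __post_init__(self):
        if self.mrr_all_states <= 0 or self.mrr_suicide_depression <= 0:
            raise ParameterValidationError("mortality rate ratios must be positive")
        if self.combination not in ("multiplicative", "additive-on-rate"):
            raise ParameterValidationError(
                f"combination must be 'multiplicative' or 'additive-on-rate', "
                f"got {self.combination!r}"
            )


@dataclass(frozen=True)
class CostTable:
    """Per-state, per-component cost inputs in 2021 EUR per quarterly cycle.

    ``per_state`` maps alive-state name -> component -> amount.  Productivity
    losses are counted only below the retirement age.
    """

    per_state: dict[str, dict[str, float]]
    retirement_age: int = 67

    def __post_init__(self):
        expected_states = {s.value for s in ALIVE_STATES}
        if set(self.per_state) != expected_states:
            raise ParameterValidationError(
                f"cost table must cover states {sorted(expected_states)}, "
                f"got {sorted(self.per_state)}"
            )
        for state, comps in self.per_state.items():
            unknown = set(comps) - set(COST_COMPONENTS)
            if unknown:
                raise ConfigError(f"unknown cost components for {state}: {sorted(unknown)}")
            for comp in COST_COMPONENTS:
                amount = comps.get(comp, 0.0)
                if amount < 0:
                    raise ParameterValidationError(
                        f"cost {state}/{comp} must be >= 0, got {amount}"
                    )
        if self.retirement_age < 0:
            raise ParameterValidationError("retirement_age must be >= 0")

    def component(self, state: HealthState, comp: str) -> float:
        return float(self.per_state[state.value].get(comp, 0.0))

    def state_total(self, state: HealthState, perspective: str,
                    include_productivity: bool = True) -> float:
        """Sum of the state's components under a perspective."""
        comps = perspective_components(perspective)
        total = 0.0
        for comp in comps:
            if comp == "productivity" and not include_productivity:
                continue
            total += self.component(state, comp)
        return total


def perspective_components(perspective: str) -> frozenset[str]:
    if perspective == "healthcare":
        return HEALTHCARE_COMPONENTS
    if perspective == "societal":
        return SOCIETAL_COMPONENTS
    raise ParameterValidationError(
        f"perspective must be 'healthcare' or 'societal', got {perspective!r}"
    )


@dataclass(frozen=True)
class IntensityMix:
    """Shares of patients per treatment-intensity category in each state.

    Remission care splits between low- and high-intensity outpatient care;
    mood-episode states additionally allow inpatient admission.  Used to blend
    component-level unit costs into per-state aggregates when users supply
    unit costs instead of the packaged per-state totals.
    """

    remission: dict[str, float] = field(
        default_factory=lambda: {"outpatient_low": 0.85, "outpatient_high": 0.15}
    )
    depression: dict[str, float] = field(
        default_factory=lambda: {"outpatient_low": 0.90, "outpatient_high": 0.07,
                                 "inpatient": 0.03}
    )
    episode: dict[str, float] = field(
        default_factory=lambda: {"outpatient_low": 0.30, "outpatient_high": 0.40,
                                 "inpatient": 0.30}
    )

    def __post_init__(self):
        for name in ("remission", "depression", "episode"):
            weights = getattr(self, name)
            allowed = {"outpatient_low", "outpatient_high"}
            if name != "remission":
                allowed.add("inpatient")
            unknown = set(weights) - allowed
            if unknown:
                raise ConfigError(f"unknown intensity categories for {name}: {sorted(unknown)}")
            for cat, w in weights.items():
                _check_probability(f"{name}/{cat} weight", w)
            if abs(sum(weights.values()) - 1.0) > ROW_TOL:
                raise ParameterValidationError(
                    f"intensity weights for {name} must sum to 1, got {weights}"
                )

    def blend(self, state: HealthState, unit_costs: Mapping[str, float]) -> float:
        """Weighted per-cycle cost for a state given per-category unit costs."""
        weights = getattr(self, state.value)
        missing = set(weights) - set(unit_costs)
        if missing:
            raise ConfigError(f"missing unit costs for categories: {sorted(missing)}")
        return sum(w * float(unit_costs[cat]) for cat, w in weights.items())


@dataclass(frozen=True)
class InterventionSpec:
    """An add-on intervention: relative risks on episode entry plus costs.

    ``rr_depression``/``rr_episode`` multiply the probabilities of entering
    the depression and (hypo)mania states while the effect lasts
    (``effect_cycles`` cycles from the start of the run).  ``scope`` controls
    which matrix entries are scaled: relapse-only touches the remission row,
    all-entries additionally the switch transitions between mood states.
    ``cost_per_cycle`` is charged in the intervention arm for ``cost_cycles``
    cycles, spread over the states named by ``cost_states``.
    """

    rr_depression: float = 0.81
    rr_episode: float = 1.32
    cost_per_cycle: float = 291.0
    effect_cycles: int = 4
    cost_cycles: int = 1
    scope: str = "relapse-only"  # or "all-entries"
    cost_states: str = "alive"  # or "remission"

    def __post_init__(self):
        if self.rr_depression <= 0 or self.rr_episode <= 0:
            raise ParameterValidationError("relative risks must be > 0")
        if self.cost_per_cycle < 0:
            raise ParameterValidationError("cost_per_cycle must be >= 0")
        if self.effect_cycles < 0 or self.cost_cycles < 0:
            raise ParameterValidationError("durations must be >= 0 cycles")
        if self.scope not in ("relapse-only", "all-entries"):
            raise ParameterValidationError(f"unknown rr scope {self.scope!r}")
        if self.cost_states not in ("alive", "remission"):
            raise ParameterValidationError(f"unknown cost_states {self.cost_states!r}")

    @classmethod
    def null(cls) -> "InterventionSpec":
        """A do-nothing intervention (RRs 1, zero cost)."""
        return cls(rr_depression=1.0, rr_episode=1.0, cost_per_cycle=0.0,
                   effect_cycles=0, cost_cycles=0)


DEFAULT_WTP_GRID = tuple(sorted(set(range(0, 200_001, 5_000)) | {147_300}))


@dataclass(frozen=True)
class ModelSettings:
    """Run settings: cycle length, horizon, discounting, start conditions."""

    cycle_length_years: float = 0.25
    horizon: str | int = "lifetime"  # "lifetime" or a fixed number of cycles
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    start_age: int = 40
    start_distribution: tuple[float, float, float] = (1.0, 0.0, 0.0)
    perspective: str = "societal"
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    half_cycle_correction: bool = True
    psa_iterations: int = 5000
    seed: int = 2021

    def __post_init__(self):
        if self.cycle_length_years <= 0:
            raise ParameterValidationError("cycle_length_years must be > 0")
        if isinstance(self.horizon, str):
            if self.horizon != "lifetime":
                raise ParameterValidationError(
                    f"horizon must be 'lifetime' or a positive cycle count, "
                    f"got {self.horizon!r}"
                )
        else:
            if int(self.horizon) != self.horizon or self.horizon <= 0:
                raise ParameterValidationError("fixed horizon must be a positive integer")
            object.__setattr__(self, "horizon", int(self.horizon))
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ParameterValidationError("discount rates must be >= 0")
        if self.start_age < 0:
            raise ParameterValidationError("start_age must be >= 0")
        dist = tuple(float(x) for x in self.start_distribution)
        object.__setattr__(self, "start_distribution", _check_row("start_distribution", dist))
        perspective_components(self.perspective)
        grid = tuple(float(x) for x in self.wtp_grid)
        if any(x < 0 for x in grid) or list(grid) != sorted(grid):
            raise ParameterValidationError("wtp_grid must be nonnegative and ascending")
        object.__setattr__(self, "wtp_grid", grid)
        if self.psa_iterations < 1:
            raise ParameterValidationError("psa_iterations must be >= 1")


@dataclass(frozen=True)
class UncertaintySpec:
    """PSA dispersions per parameter class.

    Transition rows are Dirichlet with concentration = mean row x
    ``transition_ess`` (an effective sample size; ``inf`` pins rows to their
    means).  Costs are gamma with the given coefficient of variation,
    utilities beta with the given standard error, and rate ratios lognormal
    with the given log-scale SD; a dispersion of 0 degenerates to the mean.
    """

    transition_ess: float = 100.0
    cost_cv: float = 0.2
    utility_se: float = 0.05
    rr_log_sd: float = 0.1

    def __post_init__(self):
        if not (self.transition_ess > 0):  # inf allowed
            raise ParameterValidationError("transition_ess must be > 0 (inf pins rows)")
        for name in ("cost_cv", "utility_se", "rr_log_sd"):
            if getattr(self, name) < 0:
                raise ParameterValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Complete model parameterization for both subtypes."""

    bd1: SubtypeParameters
    bd2: SubtypeParameters
    mortality: MortalityParameters
    costs: CostTable
    intervention: InterventionSpec
    settings: ModelSettings
    uncertainty: UncertaintySpec
    intensity_mix: IntensityMix = field(default_factory=IntensityMix)

    def __post_init__(self):
        total = self.bd1.prevalence_weight + self.bd2.prevalence_weight
        if abs(total - 1.0) > ROW_TOL:
            raise ParameterValidationError(
                f"subtype prevalence weights must sum to 1, got {total:.12g}"
            )

    @property
    def subtypes(self) -> tuple[SubtypeParameters, SubtypeParameters]:
        return (self.bd1, self.bd2)

    def to_dict(self) -> dict[str, Any]:
        def sub(s: SubtypeParameters) -> dict[str, Any]:
            return {
                "prevalence_weight": s.prevalence_weight,
                "remission_row": list(s.remission_row),
                "depression_row": list(s.depression_row),
                "episode_row": list(s.episode_row),
                "depression_mania_ratio": s.depression_mania_ratio,
                "time_in_depression": s.time_in_depression,
                "time_in_mania": s.time_in_mania,
                "utilities": {
                    "remission": s.utility_remission,
                    "depression": s.utility_depression,
                    "episode": s.utility_episode,
                },
            }

        return {
            "subtypes": {"bd1": sub(self.bd1), "bd2": sub(self.bd2)},
            "mortality": {
                "mrr_all_states": self.mortality.mrr_all_states,
                "mrr_suicide_depression": self.mortality.mrr_suicide_depression,
                "combination": self.mortality.combination,
            },
            "costs": {
                "retirement_age": self.costs.retirement_age,
                "per_state": {
                    state: {c: self.costs.per_state[state].get(c, 0.0)
                            for c in COST_COMPONENTS}
                    for state in self.costs.per_state
                },
            },
            "intervention": {
                "rr_depression": self.intervention.rr_depression,
                "rr_episode": self.intervention.rr_episode,
                "cost_per_cycle": self.intervention.cost_per_cycle,
                "effect_cycles": self.intervention.effect_cycles,
                "cost_cycles": self.intervention.cost_cycles,
                "scope": self.intervention.scope,
                "cost_states": self.intervention.cost_states,
            },
            "settings": {
                "cycle_length_years": self.settings.cycle_length_years,
                "horizon": self.settings.horizon,
                "discount_rate_costs": self.settings.discount_rate_costs,
                "discount_rate_effects": self.settings.discount_rate_effects,
                "start_age": self.settings.start_age,
                "start_distribution": list(self.settings.start_distribution),
                "perspective": self.settings.perspective,
                "wtp_grid": list(self.settings.wtp_grid),
                "half_cycle_correction": self.settings.half_cycle_correction,
                "psa_iterations": self.settings.psa_iterations,
                "seed": self.settings.seed,
            },
            "uncertainty": {
                "transition_ess": self.uncertainty.transition_ess,
                "cost_cv": self.uncertainty.cost_cv,
                "utility_se": self.uncertainty.utility_se,
                "rr_log_sd": self.uncertainty.rr_log_sd,
            },
            "intensity_mix": {
                "remission": dict(self.intensity_mix.remission),
                "depression": dict(self.intensity_mix.depression),
                "episode": dict(self.intensity_mix.episode),
            },
        }


def default_parameters() -> ParameterSet:
    """The packaged default parameterization (quarterly cycle, 2021 EUR).

    Transition rows are under the standard of care; rows are ordered
    (to remission, to depression, to episode).
    """
    bd1 = SubtypeParameters(
        subtype="BD-I",
        prevalence_weight=0.600,
        remission_row=(0.880, 0.094, 0.026),
        depression_row=(0.365, 0.561, 0.074),
        episode_row=(0.628, 0.074, 0.298),
        depression_mania_ratio=4.7,
        time_in_depression=0.744,
        time_in_mania=0.256,
        utility_remission=0.800,
        utility_depression=0.290,
        utility_episode=0.540,
    )
    bd2 = SubtypeParameters(
        subtype="BD-II",
        prevalence_weight=0.400,
        remission_row=(0.880, 0.117, 0.003),
        depression_row=(0.365, 0.561, 0.074),
        episode_row=(0.878, 0.074, 0.048),
        depression_mania_ratio=10.7,
        time_in_depression=0.792,
        time_in_mania=0.208,
        utility_remission=0.800,
        utility_depression=0.290,
        utility_episode=0.800,  # hypomania valued as remission
    )
    costs = CostTable(
        per_state={
            "remission": {
                "drugs": 39.0,
                "medical_services": 161.0,
                "psychological_treatment": 271.0,
                "home_based_treatment": 131.0,
                "indirect_medical": 40.0,
                "productivity": 443.0,
                "patient_family": 0.0,
                "admission": 0.0,
            },
            "depression": {
                "drugs": 53.0,
                "medical_services": 786.0,
                "psychological_treatment": 126.0,
                "home_based_treatment": 153.0,
                "indirect_medical": 40.0,
                "productivity": 3637.0,
                "patient_family": 4996.0,
                "admission": 617.0,
            },
            "episode": {
                "drugs": 53.0,
                "medical_services": 804.0,
                "psychological_treatment": 722.0,
                "home_based_treatment": 874.0,
                "indirect_medical": 40.0,
                "productivity": 2182.0,
                "patient_family": 2997.0,
                "admission": 6166.0,
            },
        },
        retirement_age=67,
    )
    return ParameterSet(
        bd1=bd1,
        bd2=bd2,
        mortality=MortalityParameters(),
        costs=costs,
        intervention=InterventionSpec(),
        settings=ModelSettings(),
        uncertainty=UncertaintySpec(),
        intensity_mix=IntensityMix(),
    )


def _merge(defaults: dict, override: Mapping, path: str = "") -> dict:
    """Deep-merge override onto defaults; unknown keys are an error."""
    merged = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{where} must be a mapping")
            merged[key] = _merge(defaults[key], value, where)
        else:
            merged[key] = value
    return merged


def _from_dict(data: dict[str, Any]) -> ParameterSet:
    def sub(tag: str, d: dict[str, Any]) -> SubtypeParameters:
        u = d["utilities"]
        return SubtypeParameters(
            subtype=tag,
            prevalence_weight=d["prevalence_weight"],
            remission_row=tuple(d["remission_row"]),
            depression_row=tuple(d["depression_row"]),
            episode_row=tuple(d["episode_row"]),
            depression_mania_ratio=d["depression_mania_ratio"],
            time_in_depression=d["time_in_depression"],
            time_in_mania=d["time_in_mania"],
            utility_remission=u["remission"],
            utility_depression=u["depression"],
            utility_episode=u["episode"],
        )

    s = data["settings"]
    return ParameterSet(
        bd1=sub("BD-I", data["subtypes"]["bd1"]),
        bd2=sub("BD-II", data["subtypes"]["bd2"]),
        mortality=MortalityParameters(**data["mortality"]),
        costs=CostTable(
            per_state={k: dict(v) for k, v in data["costs"]["per_state"].items()},
            retirement_age=data["costs"]["retirement_age"],
        ),
        intervention=InterventionSpec(**data["intervention"]),
        settings=ModelSettings(
            cycle_length_years=s["cycle_length_years"],
            horizon=s["horizon"],
            discount_rate_costs=s["discount_rate_costs"],
            discount_rate_effects=s["discount_rate_effects"],
            start_age=s["start_age"],
            start_distribution=tuple(s["start_distribution"]),
            perspective=s["perspective"],
            wtp_grid=tuple(s["wtp_grid"]),
            half_cycle_correction=s["half_cycle_correction"],
            psa_iterations=s["psa_iterations"],
            seed=s["seed"],
        ),
        uncertainty=UncertaintySpec(**data["uncertainty"]),
        intensity_mix=IntensityMix(**{k: dict(v) for k, v in data["intensity_mix"].items()}),
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a YAML config, filling unspecified fields with packaged defaults.

    Unknown keys raise :class:`ConfigError` (catches typos); invariant
    violations raise :class:`ParameterValidationError` naming the offender.
    An empty file yields :func:`default_parameters` exactly.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    merged = _merge(default_parameters().to_dict(), raw)
    return _from_dict(merged)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a parameter set to YAML (round-trips through load)."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
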