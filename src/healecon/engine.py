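"""Lifetime Markov cohort engine over the 793 states.

A cohort enters at age 10 distributed over the 24 risk profiles (after the
program effect, if any) with no chronic disease.  Each cycle, in this fixed
order:

1. mortality — every alive state dies with p = 1 - exp(-h* t), where h* is
   the life-table hazard scaled by the standardized mortality ratios of the
   state's risk-factor levels and disease status;
2. disease incidence — survivors without chronic disease acquire one of the
   32 diseases under competing risks: total probability 1 - exp(-sum_d I*_d t)
   allocated proportionally to the risk-adjusted incidences I*_d;
3. risk-factor transition — the joint profile evolves by the annualized
   transition matrix, in diseased and disease-free states alike.

Disease states never revert; Dead is absorbing.  Person-time is credited at
the start-of-cycle occupancy, discounted at (1 + r)^(-years since entry)
(year 0 undiscounted); no half-cycle correction by default.

Female and male cohorts run in parallel and are combined by a configurable
mix.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .epi import CategoryRatios, standardize_ratios
from .program_effects import JointRiskDistribution, ProgramEffect, apply_program_effect
from .state_space import (
    DEAD_INDEX,
    FACTORS,
    FACTOR_LEVELS,
    N_DISEASES,
    N_DISEASE_STATUS,
    N_PROFILES,
    N_STATES,
    enumerate_profiles,
)
from .transitions import TransitionCoefficients, per_cycle_matrix

SEXES = ("female", "male")
_SEX_CODE = {"female": 0, "male": 1}


def discount_factor(rate: float, years_elapsed: float) -> float:
    """(1 + rate)^(-years); outcomes in the entry year are undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return float((1.0 + rate) ** (-years_elapsed))


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """All-cause mortality hazard per year by integer age and sex."""

    ages: np.ndarray
    hazards: Mapping[str, np.ndarray]  # per sex, aligned with ages

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        hazards = {k: np.asarray(v, dtype=float) for k, v in self.hazards.items()}
        for sex in SEXES:
            if sex not in hazards:
                raise ValueError(f"life table missing sex {sex!r}")
            if hazards[sex].shape != ages.shape:
                raise ValueError("hazard column must align with ages")
            if (hazards[sex] < 0).any():
                raise ValueError("hazards must be non-negative")
        if (np.diff(ages) <= 0).any():
            raise ValueError("ages must be strictly increasing")
        object.__setattr__(self, "hazards", hazards)

    def hazard(self, sex: str, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise ValueError(f"age {age} outside life-table support "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        return float(np.interp(age, self.ages, self.hazards[sex]))


@dataclasses.dataclass
class AgeRateCurve:
    """Annual rate on an age grid per sex, linearly interpolated."""

    ages: np.ndarray
    values: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for sex, v in self.values.items():
            if v.shape != self.ages.shape:
                raise ValueError("rate values must align with the age grid")
            if (v < 0).any():
                raise ValueError("rates must be non-negative")

    def at(self, sex: str, age: float) -> float:
        return float(np.interp(age, self.ages, self.values[sex]))

    @classmethod
    def constant(cls, value: float, ages=(0.0, 110.0)) -> "AgeRateCurve":
        ages = np.asarray(ages, dtype=float)
        return cls(ages, {s: np.full_like(ages, value) for s in SEXES})


@dataclasses.dataclass
class DiseaseSpec:
    """One chronic disease: linked relative risks, incidence, mortality,
    utility decrement and annual attributable cost."""

    disease_id: int  # 1..32
    name: str
    relative_risks: Mapping[str, np.ndarray]  # per factor, ref category = 1
    incidence: AgeRateCurve
    mortality_ratio: float
    prevalence: float
    utility_decrement: float
    annual_cost: float

    def __post_init__(self) -> None:
        if not 1 <= self.disease_id <= N_DISEASES:
            raise ValueError("disease_id must be in 1..32")
        rrs = {}
        for factor in FACTORS:
            rr = np.asarray(self.relative_risks.get(factor, np.ones(FACTOR_LEVELS[factor])),
                            dtype=float)
            if rr.shape != (FACTOR_LEVELS[factor],):
                raise ValueError(f"{factor} relative risks need {FACTOR_LEVELS[factor]} entries")
            if (rr <= 0).any():
                raise ValueError("relative risks must be positive")
            if rr[0] != 1.0:
                raise ValueError("reference category relative risk must be 1")
            rrs[factor] = rr
        self.relative_risks = rrs
        if self.mortality_ratio <= 0:
            raise ValueError("mortality ratio must be positive")
        if not 0 <= self.prevalence < 1:
            raise ValueError("prevalence must be in [0, 1)")
        if not 0 <= self.utility_decrement <= 1:
            raise ValueError("utility decrement must be in [0, 1]")
        if self.annual_cost < 0:
            raise ValueError("annual cost must be non-negative")


@dataclasses.dataclass
class ModelParameters:
    """Everything a cohort run needs."""

    initial: JointRiskDistribution
    coefficients: TransitionCoefficients
    diseases: Sequence[DiseaseSpec]  # 32, ordered by disease_id
    life_table: LifeTable
    mortality_rate_ratios: Mapping[str, np.ndarray]  # per factor, ref = 1
    risk_proportions: Mapping[str, np.ndarray]  # population P_k per factor
    weight_decrements: tuple[float, float] = (0.0, 0.0)  # overweight, obese
    discount_rate: float = 0.015
    horizon_years: int = 84
    cycle_years: int = 1
    start_age: int = 10
    sex_mix: float = 0.5  # fraction female

    def __post_init__(self) -> None:
        self.diseases = list(self.diseases)
        if len(self.diseases) != N_DISEASES:
            raise ValueError(f"expected {N_DISEASES} disease specs")
        for i, d in enumerate(self.diseases, start=1):
            if d.disease_id != i:
                raise ValueError("disease specs must be ordered by disease_id 1..32")
        for factor in FACTORS:
            mr = np.asarray(self.mortality_rate_ratios[factor], dtype=float)
            pk = np.asarray(self.risk_proportions[factor], dtype=float)
            if mr.shape != (FACTOR_LEVELS[factor],) or pk.shape != (FACTOR_LEVELS[factor],):
                raise ValueError(f"{factor} ratios/proportions have the wrong length")
            if (mr <= 0).any():
                raise ValueError("mortality rate ratios must be positive")
            CategoryRatios(mr, pk)  # validates proportions
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.cycle_years not in (1, 2):
            raise ValueError("cycle length must be 1 or 2 years")
        if self.horizon_years % self.cycle_years:
            raise ValueError("horizon must be a multiple of the cycle length")
        if not 0 <= self.sex_mix <= 1:
            raise ValueError("sex mix must be in [0, 1]")
        if not 0 <= self.weight_decrements[0] <= 1 or not 0 <= self.weight_decrements[1] <= 1:
            raise ValueError("weight decrements must be in [0, 1]")
        total_prev = sum(d.prevalence for d in self.diseases)
        if total_prev >= 1:
            raise ValueError("disease prevalences sum to >= 1")

    @property
    def n_cycles(self) -> int:
        return self.horizon_years // self.cycle_years

    def cycle_ages(self) -> np.ndarray:
        return self.start_age + self.cycle_years * np.arange(self.n_cycles)


@dataclasses.dataclass
class CohortTrace:
    """Occupancy and discounted person-time per Markov state per cycle.

    ``occupancy`` holds start-of-cycle snapshots (n_cycles + 1 rows of length
    793, the last being the end-of-horizon state); ``discounted_time`` holds
    the discounted person-time credited in each of the n_cycles cycles.
    """

    occupancy: np.ndarray
    discounted_time: np.ndarray
    start_age: int
    cycle_years: int
    discount_rate: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles+1, {N_STATES})")
        sums = occ.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-10:
            raise ValueError("occupancy rows must each sum to 1")
        if (np.diff(occ[:, DEAD_INDEX]) < -1e-12).any():
            raise ValueError("Dead occupancy must be non-decreasing")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive_fraction(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD_INDEX]

    def mix(self, other: "CohortTrace", weight_self: float) -> "CohortTrace":
        w = weight_self
        return CohortTrace(
            w * self.occupancy + (1 - w) * other.occupancy,
            w * self.discounted_time + (1 - w) * other.discounted_time,
            self.start_age,
            self.cycle_years,
            self.discount_rate,
        )


def competing_incidence(rates_times_t: np.ndarray) -> tuple[np.ndarray, float]:
    """Allocate one cycle's incidence among competing diseases.

    Given per-disease cumulative rates I*_d * t, the probability of any
    incident disease is 1 - exp(-sum_d I*_d t), shared proportionally to the
    rates; the stay probability is exp(-sum).  Returns (per-disease
    probabilities, stay probability); everything sums to 1.
    """
    rates = np.asarray(rates_times_t, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    total = rates.sum()
    stay = float(np.exp(-total))
    if total <= 0:
        return np.zeros_like(rates), 1.0
    p_any = -np.expm1(-total)
    return rates * (p_any / total), stay


def _standardized_profile_multipliers(
    ratios: Mapping[str, np.ndarray], proportions: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Product over factors of standardized ratios, per profile (24,)."""
    out = np.ones(N_PROFILES)
    for factor in FACTORS:
        smr = standardize_ratios(CategoryRatios(ratios[factor], proportions[factor]))
        levels = np.array([p.level(factor) for p in enumerate_profiles()])
        out *= smr[levels]
    return out


def _disease_smr(params: ModelParameters) -> np.ndarray:
    """Standardized mortality ratio per disease status (33,)."""
    prev = np.array([d.prevalence for d in params.diseases])
    proportions = np.concatenate([[1.0 - prev.sum()], prev])
    ratios = np.concatenate([[1.0], [d.mortality_ratio for d in params.diseases]])
    return standardize_ratios(CategoryRatios(ratios, proportions))


def _incidence_multipliers(params: ModelParameters) -> np.ndarray:
    """Standardized relative-risk product per (disease, profile): (32, 24)."""
    out = np.ones((N_DISEASES, N_PROFILES))
    for d, spec in enumerate(params.diseases):
        out[d] = _standardized_profile_multipliers(spec.relative_risks, params.risk_proportions)
    return out


def transition_tables(params: ModelParameters) -> dict[str, list[np.ndarray]]:
    """Per-cycle transition matrices for every cycle age, per sex.

    Precomputing these lets several scenario runs (which differ only in the
    initial distribution) share the annualization work.
    """
    tables: dict[str, list[np.ndarray]] = {}
    for sex in SEXES:
        tables[sex] = [
            per_cycle_matrix(params.coefficients, _SEX_CODE[sex], float(age), params.cycle_years)
            for age in params.cycle_ages()
        ]
    return tables


def _run_single_sex(
    params: ModelParameters,
    init: np.ndarray,
    sex: str,
    matrices: Sequence[np.ndarray],
) -> CohortTrace:
    t = float(params.cycle_years)
    n_cycles = params.n_cycles
    mortality_mult = (
        _standardized_profile_multipliers(params.mortality_rate_ratios, params.risk_proportions)[
            :, None
        ]
        * _disease_smr(params)[None, :]
    )  # (24, 33)
    inc_mult = _incidence_multipliers(params)  # (32, 24)

    occ = np.zeros((N_PROFILES, N_DISEASE_STATUS))
    occ[:, 0] = init
    dead = 0.0
    snapshots = np.zeros((n_cycles + 1, N_STATES))

    for k, age in enumerate(params.cycle_ages()):
        snapshots[k, :DEAD_INDEX] = occ.T.reshape(-1)
        snapshots[k, DEAD_INDEX] = dead

        # 1. mortality
        H = params.life_table.hazard(sex, float(age))
        surv = np.exp(-H * mortality_mult * t)
        dead += float((occ * (1.0 - surv)).sum())
        occ = occ * surv

        # 2. competing disease incidence among the disease-free
        base_inc = np.array([d.incidence.at(sex, float(age)) for d in params.diseases])
        rates_t = (base_inc[:, None] * inc_mult).T * t  # (24, 32)
        total = rates_t.sum(axis=1)
        stay = np.exp(-total)
        with np.errstate(invalid="ignore", divide="ignore"):
            alloc = np.where(total > 0, -np.expm1(-total) / total, 0.0)
        new_cases = occ[:, 0:1] * rates_t * alloc[:, None]
        occ[:, 1:] += new_cases
        occ[:, 0] *= stay

        # 3. joint risk-factor transition (same model in all disease states)
        occ = matrices[k].T @ occ

    snapshots[n_cycles, :DEAD_INDEX] = occ.T.reshape(-1)
    snapshots[n_cycles, DEAD_INDEX] = dead

    cycles = np.arange(n_cycles)
    df = (1.0 + params.discount_rate) ** (-(cycles * t))
    discounted = snapshots[:-1] * t * df[:, None]
    return CohortTrace(snapshots, discounted, params.start_age, params.cycle_years,
                       params.discount_rate)


def run_cohort(
    params: ModelParameters,
    effect: ProgramEffect | None = None,
    matrices: dict[str, list[np.ndarray]] | None = None,
) -> CohortTrace:
    """Run the lifetime cohort under a program effect (or none).

    The program effect acts once, on the age-10 joint distribution; it does
    not alter transition probabilities.  ``matrices`` may carry precomputed
    :func:`transition_tables` output to share work across scenarios.
    """
    dist = params.initial
    if effect is not None:
        dist = apply_program_effect(dist, effect)
    init = dist.as_array()
    if matrices is None:
        matrices = transition_tables(params)
    traces = {
        sex: _run_single_sex(params, init, sex, matrices[sex]) for sex in SEXES
    }
    return traces["female"].mix(traces["male"], params.sex_mix)
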