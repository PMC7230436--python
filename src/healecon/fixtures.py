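"""Synthetic, internally consistent model parameter sets.

The generator emulates the *shape* of the national inputs the model consumes
— a Gompertz-like life table, an age-10 joint risk-factor distribution with
realistic marginals and mild interdependence, sticky two-year joint
transitions, and 32 disease specifications whose relative-risk pattern
matches the packaged disease/risk-factor linkage table exactly (relative
risk 1 wherever no link exists) — without claiming calibration to any
particular country.  Everything is a pure function of the seed.

Conventions baked into the draws: harmful categories (overweight, obese) get
relative risks and mortality ratios above 1; protective behavioural
categories (meeting activity/fruit/vegetable recommendations) get ratios
below 1, so that beneficial program effects act in the beneficial direction.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .engine import AgeRateCurve, DiseaseSpec, LifeTable, ModelParameters, SEXES
from .program_effects import JointRiskDistribution
from .state_space import FACTORS, FACTOR_LEVELS, N_DISEASES, load_linkage
from .transitions import Term, TransitionCoefficients, default_structure

AGE_GRID = np.arange(0.0, 111.0, 5.0)


@dataclasses.dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic parameter generator (seed is mandatory)."""

    seed: int
    hazard_scale: float = 3e-5  # Gompertz h0 (per year at age 0)
    hazard_age_slope: float = 0.09  # Gompertz log-slope per year of age
    incidence_scale: tuple[float, float] = (1e-5, 2e-3)  # log-uniform base range
    rr_harmful: tuple[float, float] = (1.1, 2.0)  # overweight/obese RRs
    rr_protective: tuple[float, float] = (0.55, 0.95)  # meeting-recommendation RRs
    mortality_ratio_range: tuple[float, float] = (1.1, 2.5)  # diseased vs not
    decrement_range: tuple[float, float] = (0.02, 0.25)
    cost_range: tuple[float, float] = (1_000.0, 15_000.0)
    initial_concentration: float = 300.0  # Dirichlet effective sample size
    transition_persistence: float = 2.2  # own-status log-odds carryover

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("hazard_scale", "hazard_age_slope", "initial_concentration",
                     "transition_persistence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _life_table(config: FixtureConfig, rng: np.random.Generator) -> LifeTable:
    hazards = {}
    sex_mult = {"female": 0.85, "male": 1.15}
    for sex in SEXES:
        h = config.hazard_scale * sex_mult[sex] * np.exp(config.hazard_age_slope * AGE_GRID)
        hazards[sex] = np.minimum(h + 1e-4, 0.9)
    return LifeTable(AGE_GRID, hazards)


def _initial_distribution(
    config: FixtureConfig, rng: np.random.Generator
) -> JointRiskDistribution:
    # plausible age-10 marginals: most children normal weight, few meeting
    # activity recommendations, about a third meeting fruit/vegetable ones
    marginals = {
        "weight": np.array([0.68, 0.20, 0.12]),
        "activity": np.array([0.80, 0.20]),
        "fruit": np.array([0.65, 0.35]),
        "vegetable": np.array([0.70, 0.30]),
    }
    # independent product, then Dirichlet jitter to induce interdependence
    prod = np.einsum(
        "w,p,f,v->wpfv",
        marginals["weight"],
        marginals["activity"],
        marginals["fruit"],
        marginals["vegetable"],
    ).reshape(-1)
    probs = rng.dirichlet(config.initial_concentration * prod)
    return JointRiskDistribution(probs)


def _transition_coefficients(
    config: FixtureConfig, rng: np.random.Generator
) -> TransitionCoefficients:
    terms = default_structure()
    values = np.zeros(len(terms))
    own = {"w1": "cw1", "w2": "cw2", "p1": "cp1", "f1": "cf1", "v1": "cv1"}
    for j, term in enumerate(terms):
        if len(term.outcomes) == 1:
            o = term.outcomes[0]
            if term.covariate is None:
                values[j] = rng.normal(-1.6, 0.3)  # rare to switch into a status
            elif term.covariate == own[o]:
                values[j] = rng.normal(config.transition_persistence, 0.2)
            elif term.covariate == "age":
                values[j] = rng.normal(0.15, 0.1)
            elif term.covariate == "sex":
                values[j] = rng.normal(0.0, 0.1)
            else:  # cross current-status effects
                values[j] = rng.normal(0.0, 0.15)
        else:  # outcome-component associations
            values[j] = rng.normal(0.0, 0.2)
    return TransitionCoefficients(terms, values)


def _disease_specs(config: FixtureConfig, rng: np.random.Generator) -> list[DiseaseSpec]:
    linkage = load_linkage()
    specs = []
    lo_i, hi_i = config.incidence_scale
    for d in range(1, N_DISEASES + 1):
        rrs = {}
        for factor in FACTORS:
            rr = np.ones(FACTOR_LEVELS[factor])
            if linkage.is_linked(d, factor):
                if factor == "weight":
                    ow = rng.uniform(*config.rr_harmful)
                    ob = rng.uniform(ow, config.rr_harmful[1] * 1.4)
                    rr = np.array([1.0, ow, ob])
                else:
                    rr = np.array([1.0, rng.uniform(*config.rr_protective)])
            rrs[factor] = rr
        base = np.exp(rng.uniform(np.log(lo_i), np.log(hi_i)))
        slope = rng.uniform(0.0, 0.05)
        curve_values = {}
        for sex in SEXES:
            mult = rng.uniform(0.7, 1.3)
            curve_values[sex] = np.minimum(base * mult * np.exp(slope * (AGE_GRID - 50.0)), 0.05)
        specs.append(
            DiseaseSpec(
                disease_id=d,
                name=linkage.names[d - 1],
                relative_risks=rrs,
                incidence=AgeRateCurve(AGE_GRID, curve_values),
                mortality_ratio=rng.uniform(*config.mortality_ratio_range),
                prevalence=rng.uniform(0.002, 0.02),
                utility_decrement=rng.uniform(*config.decrement_range),
                annual_cost=rng.uniform(*config.cost_range),
            )
        )
    return specs


def generate_parameter_set(config: FixtureConfig) -> ModelParameters:
    """A complete, valid, reproducible synthetic parameter set."""
    rng = np.random.default_rng(config.seed)
    initial = _initial_distribution(config, rng)
    risk_proportions = {f: initial.marginal(f) for f in FACTORS}
    mortality_ratios = {
        "weight": np.array([1.0, rng.uniform(1.05, 1.2), rng.uniform(1.2, 1.6)]),
        "activity": np.array([1.0, rng.uniform(0.7, 0.95)]),
        "fruit": np.array([1.0, rng.uniform(0.8, 0.98)]),
        "vegetable": np.array([1.0, rng.uniform(0.8, 0.98)]),
    }
    return ModelParameters(
        initial=initial,
        coefficients=_transition_coefficients(config, rng),
        diseases=_disease_specs(config, rng),
        life_table=_life_table(config, rng),
        mortality_rate_ratios=mortality_ratios,
        risk_proportions=risk_proportions,
        weight_decrements=(rng.uniform(0.005, 0.03), rng.uniform(0.03, 0.08)),
    )


def generate_null_parameter_set(config: FixtureConfig) -> ModelParameters:
    """A degenerate set in which risk factors and diseases are inert.

    All relative risks and mortality ratios are 1, every incidence is 0 and
    every decrement is 0, so cohort survival collapses to the life table and
    QALYs to discounted life expectancy — the closed-form limit used by the
    engine's property tests.
    """
    params = generate_parameter_set(config)
    null_diseases = [
        DiseaseSpec(
            disease_id=d.disease_id,
            name=d.name,
            relative_risks={f: np.ones(FACTOR_LEVELS[f]) for f in FACTORS},
            incidence=AgeRateCurve.constant(0.0, AGE_GRID),
            mortality_ratio=1.0,
            prevalence=d.prevalence,
            utility_decrement=0.0,
            annual_cost=0.0,
        )
        for d in params.diseases
    ]
    return ModelParameters(
        initial=params.initial,
        coefficients=params.coefficients,
        diseases=null_diseases,
        life_table=params.life_table,
        mortality_rate_ratios={f: np.ones(FACTOR_LEVELS[f]) for f in FACTORS},
        risk_proportions=params.risk_proportions,
        weight_decrements=(0.0, 0.0),
        discount_rate=params.discount_rate,
        horizon_years=params.horizon_years,
        cycle_years=params.cycle_years,
        start_age=params.start_age,
        sex_mix=params.sex_mix,
    )
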