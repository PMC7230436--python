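"""Probabilistic sensitivity analysis.

Parameters are re-drawn per simulation from the conventional families —
beta for prevalences and incidences, log-normal (median at the point
estimate) for relative risks and mortality rate ratios, normal for the
transition-model coefficients — the scenario comparison is re-run on each
draw, and the 2.5th/97.5th percentiles of each output across simulations
form the 95% interval.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import copy
import dataclasses
import logging

import numpy as np

from .engine import ModelParameters, SEXES
from .outcomes import ScenarioComparison, compare_scenarios
from .program_effects import JointRiskDistribution, ProgramEffect
from .state_space import FACTORS

logger = logging.getLogger(__name__)


def beta_hyperparameters(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta(a, b) for a proportion with the given mean and sd."""
    if not 0 < mean < 1:
        raise ValueError("mean must be strictly inside (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("sd too large for a beta distribution with this mean")
    return mean * nu, (1 - mean) * nu


def beta_from_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Beta hyperparameters from a point estimate and a 95% interval."""
    return beta_hyperparameters(mean, (hi - lo) / 3.92)


def lognormal_from_ci(point: float, lo: float, hi: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with median ``point`` and 95% CI (lo, hi)."""
    if min(point, lo, hi) <= 0 or hi <= lo:
        raise ValueError("need positive values with hi > lo")
    return float(np.log(point)), float((np.log(hi) - np.log(lo)) / 3.92)


@dataclasses.dataclass(frozen=True)
class UncertaintySpec:
    """Dispersion of each parameter group (zero everywhere = no uncertainty).

    ``incidence_cv``/``prevalence_cv`` are coefficients of variation feeding
    moment-matched beta draws; ``rr_log_sd``/``mortality_ratio_log_sd`` are
    log-scale standard deviations of log-normal draws with median at the
    point estimate (reference categories stay fixed at 1);
    ``coefficient_sd`` is the normal standard deviation added to each
    transition-model coefficient; ``initial_dist_ess`` is the effective
    sample size behind per-cell beta draws of the 24-cell initial
    distribution (0 disables).
    """

    incidence_cv: float = 0.0
    prevalence_cv: float = 0.0
    rr_log_sd: float = 0.0
    mortality_ratio_log_sd: float = 0.0
    coefficient_sd: float = 0.0
    initial_dist_ess: float = 0.0

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_null(self) -> bool:
        return all(v == 0.0 for v in dataclasses.asdict(self).values())

    @classmethod
    def from_dict(cls, data: dict) -> "UncertaintySpec":
        return cls(**{k: float(v) for k, v in data.items()})


def _draw_lognormal(values: np.ndarray, log_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal jitter; entries equal to 1 (references and
    unlinked factors) are left untouched."""
    out = values.copy()
    active = values != 1.0
    out[active] = values[active] * np.exp(rng.normal(0.0, log_sd, active.sum()))
    return out


def _draw_beta_scalar(mean: float, cv: float, rng: np.random.Generator) -> float:
    if mean <= 0 or mean >= 1:
        return mean
    sd = cv * mean
    try:
        a, b = beta_hyperparameters(mean, sd)
    except ValueError:
        return mean
    return float(rng.beta(a, b))


def draw_parameter_set(
    base: ModelParameters, spec: UncertaintySpec, rng_seed
) -> ModelParameters:
    """One random parameter set around ``base``; exact copy for a null spec."""
    if spec.is_null:
        return base
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    params = copy.deepcopy(base)

    if spec.initial_dist_ess > 0:
        probs = params.initial.as_array()
        drawn = np.array(
            [
                rng.beta(*beta_hyperparameters(p, np.sqrt(p * (1 - p) / spec.initial_dist_ess)))
                if 0 < p < 1
                else p
                for p in probs
            ]
        )
        params.initial = JointRiskDistribution(drawn / drawn.sum())
        params.risk_proportions = {f: params.initial.marginal(f) for f in FACTORS}

    if spec.coefficient_sd > 0:
        params.coefficients.values = params.coefficients.values + rng.normal(
            0.0, spec.coefficient_sd, params.coefficients.values.shape
        )

    if spec.mortality_ratio_log_sd > 0:
        params.mortality_rate_ratios = {
            f: _draw_lognormal(np.asarray(v, dtype=float), spec.mortality_ratio_log_sd, rng)
            for f, v in params.mortality_rate_ratios.items()
        }

    for disease in params.diseases:
        if spec.rr_log_sd > 0:
            disease.relative_risks = {
                f: _draw_lognormal(rr, spec.rr_log_sd, rng)
                for f, rr in disease.relative_risks.items()
            }
        if spec.mortality_ratio_log_sd > 0:
            disease.mortality_ratio = float(
                disease.mortality_ratio * np.exp(rng.normal(0.0, spec.mortality_ratio_log_sd))
            )
        if spec.prevalence_cv > 0:
            disease.prevalence = _draw_beta_scalar(disease.prevalence, spec.prevalence_cv, rng)
        if spec.incidence_cv > 0:
            # one multiplicative draw per sex, shifting the whole age curve
            for sex in SEXES:
                curve = disease.incidence.values[sex]
                ref = float(curve.max())
                if ref <= 0:
                    continue
                drawn = _draw_beta_scalar(min(ref, 0.5), spec.incidence_cv, rng)
                disease.incidence.values[sex] = curve * (drawn / min(ref, 0.5))
    return params


@dataclasses.dataclass(frozen=True)
class PSASummary:
    """Point estimate and percentile interval for one model output."""

    name: str
    point: float
    lower: float
    upper: float
    n_sims: int
    seed: int
    point_outside_interval: bool = False


@dataclasses.dataclass
class PSAResult:
    summaries: dict[str, PSASummary]
    n_failures: int
    draws: dict[str, np.ndarray]


def run_psa(
    base: ModelParameters,
    spec: UncertaintySpec,
    effect_full: ProgramEffect,
    n_sims: int = 10_000,
    seed: int = 0,
    program_annual_cost: float = 50.0,
    program_years: int = 2,
    cost_per_disease_year=None,
) -> PSAResult:
    """Percentile intervals for ICERs, ROIs and their ratios over ``n_sims`` draws."""
    if n_sims < 2:
        raise ValueError("n_sims must be at least 2")
    from .outcomes import DEFAULT_FLAT_COST

    cost = DEFAULT_FLAT_COST if cost_per_disease_year is None else cost_per_disease_year
    kwargs = dict(
        program_annual_cost=program_annual_cost,
        program_years=program_years,
        cost_per_disease_year=cost,
    )
    point = compare_scenarios(base, effect_full, **kwargs).outputs()

    child_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    collected: dict[str, list[float]] = {k: [] for k in point}
    failures = 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        try:
            drawn = draw_parameter_set(base, spec, rng)
            out = compare_scenarios(drawn, effect_full, **kwargs).outputs()
        except Exception as exc:  # individual-draw failure: log and exclude
            failures += 1
            logger.warning("PSA draw failed and was excluded: %s", exc)
            continue
        for k, v in out.items():
            collected[k].append(v)

    if failures:
        logger.warning("PSA: %d of %d draws failed and were excluded", failures, n_sims)

    summaries = {}
    draws = {k: np.asarray(v) for k, v in collected.items()}
    for name, values in draws.items():
        lo, hi = np.percentile(values, [2.5, 97.5])
        outside = not (lo - 1e-12 <= point[name] <= hi + 1e-12)
        if outside:
            logger.warning("PSA: point estimate of %s lies outside its interval", name)
        summaries[name] = PSASummary(
            name=name,
            point=float(point[name]),
            lower=float(lo),
            upper=float(hi),
            n_sims=n_sims,
            seed=seed,
            point_outside_interval=outside,
        )
    return PSAResult(summaries=summaries, n_failures=failures, draws=draws)
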