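"""Economic outcomes: QALYs, disease-years, costs, ICERs and ROI.

Every year lived carries a utility of 1 minus the larger of the weight-status
decrement and the chronic-disease decrement for the occupied state (Dead
contributes nothing).  Health-care costs accrue per discounted person-year
with chronic disease, either at a single flat annual figure or per disease.

Scenario contrasts run three cohorts on one parameter set — baseline (no
program), weight-status-only effect (behavioural odds ratios forced to 1)
and the full four-factor effect — and report, for each non-baseline arm,
the incremental QALYs and disease-years, the ICERs (program cost only,
divided by the magnitude of the incremental effect), the savings (prevented
discounted disease-years times the annual cost) and the ROI, plus the
weight-only : full-model ratios of the ICERs and ROIs.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .engine import (
    CohortTrace,
    ModelParameters,
    discount_factor,
    run_cohort,
    transition_tables,
)
from .program_effects import ProgramEffect
from .state_space import (
    DEAD_INDEX,
    N_DISEASE_STATUS,
    N_PROFILES,
    N_STATES,
    enumerate_profiles,
)

DEFAULT_FLAT_COST = 12_174.0  # annual health-care cost attributable to chronic disease


@dataclasses.dataclass(frozen=True)
class UtilityDecrements:
    """Utility decrements on the 0-1 scale per weight status and disease."""

    weight: np.ndarray  # (3,) with weight[0] = 0
    disease: np.ndarray  # (33,) with disease[0] = 0

    def __post_init__(self) -> None:
        weight = np.asarray(self.weight, dtype=float)
        disease = np.asarray(self.disease, dtype=float)
        if weight.shape != (3,) or disease.shape != (N_DISEASE_STATUS,):
            raise ValueError("need 3 weight and 33 disease decrements")
        for arr in (weight, disease):
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("decrements must be in [0, 1]")
        if weight[0] != 0 or disease[0] != 0:
            raise ValueError("reference categories must have decrement 0")
        object.__setattr__(self, "weight", weight)
        object.__setattr__(self, "disease", disease)

    @classmethod
    def from_params(cls, params: ModelParameters) -> "UtilityDecrements":
        ow, ob = params.weight_decrements
        disease = np.concatenate([[0.0], [d.utility_decrement for d in params.diseases]])
        return cls(np.array([0.0, ow, ob]), disease)

    def per_state(self) -> np.ndarray:
        """max(weight decrement, disease decrement) per alive state; Dead -> 1."""
        weights = np.array([self.weight[p.weight] for p in enumerate_profiles()])
        out = np.empty(N_STATES)
        grid = np.maximum(weights[None, :], self.disease[:, None])  # (33, 24)
        out[:DEAD_INDEX] = grid.reshape(-1)
        out[DEAD_INDEX] = 1.0
        return out


def _disease_state_mask() -> np.ndarray:
    mask = np.zeros(N_STATES, dtype=bool)
    mask[N_PROFILES:DEAD_INDEX] = True  # disease ids 1..32
    return mask


def qaly_total(trace: CohortTrace, dec: UtilityDecrements) -> float:
    """Discounted QALYs: person-time weighted by 1 - max(decrements)."""
    utility = 1.0 - dec.per_state()
    utility[DEAD_INDEX] = 0.0
    return float((trace.discounted_time * utility).sum())


def disease_years(trace: CohortTrace) -> float:
    """Discounted person-years spent with any chronic disease."""
    return float(trace.discounted_time[:, _disease_state_mask()].sum())


def healthcare_costs(trace: CohortTrace, cost_per_case_year) -> float:
    """Discounted costs from person-time in disease states.

    ``cost_per_case_year`` is either a single flat annual figure applied to
    every disease-year, or a length-33 vector of per-disease annual costs
    (entry 0, the no-disease state, must be 0).
    """
    cost = np.asarray(cost_per_case_year, dtype=float)
    if cost.ndim == 0:
        if cost < 0:
            raise ValueError("cost must be non-negative")
        return float(cost) * disease_years(trace)
    if cost.shape != (N_DISEASE_STATUS,):
        raise ValueError("per-disease costs need 33 entries")
    if (cost < 0).any() or cost[0] != 0:
        raise ValueError("costs must be non-negative with no-disease cost 0")
    per_state = np.zeros(N_STATES)
    per_state[:DEAD_INDEX] = np.repeat(cost, N_PROFILES)
    return float((trace.discounted_time * per_state).sum())


def icer(incremental_cost: float, incremental_effect: float) -> float:
    """Incremental cost per unit effect; the effect's magnitude is used.

    Disease-years prevented enter as negative incremental effects; the ICER
    convention divides by the absolute effect and reports the sign of the
    effect separately.  A zero effect is undefined and raises.
    """
    if incremental_effect == 0:
        if incremental_cost == 0:
            return 0.0
        raise ZeroDivisionError("ICER undefined for zero incremental effect")
    return incremental_cost / abs(incremental_effect)


def roi(savings: float, program_cost: float) -> float:
    """Return on investment: savings / cost x 100 (percent)."""
    if program_cost <= 0:
        raise ValueError("program cost must be positive")
    return savings / program_cost * 100.0


def program_cost_discounted(
    annual_cost: float = 50.0, years: int = 2, rate: float = 0.015
) -> float:
    """Present value of a per-student program cost paid annually for ``years``."""
    if annual_cost < 0 or years < 1:
        raise ValueError("need non-negative cost over at least one year")
    return float(sum(annual_cost * discount_factor(rate, y) for y in range(years)))


@dataclasses.dataclass
class ScenarioResult:
    """Outcomes of one program arm against the baseline cohort."""

    qalys: float
    disease_years: float
    healthcare_cost: float
    program_cost: float
    incremental_qalys: float
    incremental_disease_years: float
    savings: float
    icer_qaly: float
    icer_disease_years: float
    roi: float


@dataclasses.dataclass
class ScenarioComparison:
    """Weight-only vs full four-factor evaluation of one program."""

    effect: ProgramEffect
    program_cost: float
    baseline_qalys: float
    baseline_disease_years: float
    weight_only: ScenarioResult
    full: ScenarioResult
    icer_qaly_ratio: float
    icer_disease_years_ratio: float
    roi_ratio: float

    def outputs(self) -> dict[str, float]:
        return {
            "icer_qaly_1": self.weight_only.icer_qaly,
            "icer_qaly_2": self.full.icer_qaly,
            "icer_qaly_ratio": self.icer_qaly_ratio,
            "icer_dy_1": self.weight_only.icer_disease_years,
            "icer_dy_2": self.full.icer_disease_years,
            "icer_dy_ratio": self.icer_disease_years_ratio,
            "roi_1": self.weight_only.roi,
            "roi_2": self.full.roi,
            "roi_ratio": self.roi_ratio,
        }


def compare_scenarios(
    params: ModelParameters,
    effect_full: ProgramEffect,
    program_annual_cost: float = 50.0,
    program_years: int = 2,
    cost_per_disease_year=DEFAULT_FLAT_COST,
) -> ScenarioComparison:
    """Contrast the weight-only and four-factor evaluations of one program.

    Runs baseline, weight-only (behavioural odds ratios forced to 1) and full
    cohorts on the same parameter set and transition tables.  Savings default
    to prevented discounted disease-years times the flat annual cost; passing
    a length-33 vector switches to per-disease costing, in which case savings
    are the avoided discounted health-care costs.
    """
    tables = transition_tables(params)
    dec = UtilityDecrements.from_params(params)
    program_cost = program_cost_discounted(
        program_annual_cost, program_years, params.discount_rate
    )

    base = run_cohort(params, None, tables)
    base_q = qaly_total(base, dec)
    base_dy = disease_years(base)
    base_hc = healthcare_costs(base, cost_per_disease_year)

    flat = np.ndim(cost_per_disease_year) == 0

    def arm(effect: ProgramEffect) -> ScenarioResult:
        trace = run_cohort(params, effect, tables)
        q = qaly_total(trace, dec)
        dy = disease_years(trace)
        hc = healthcare_costs(trace, cost_per_disease_year)
        d_q = q - base_q
        d_dy = dy - base_dy
        savings = -d_dy * float(cost_per_disease_year) if flat else base_hc - hc
        return ScenarioResult(
            qalys=q,
            disease_years=dy,
            healthcare_cost=hc,
            program_cost=program_cost,
            incremental_qalys=d_q,
            incremental_disease_years=d_dy,
            savings=savings,
            icer_qaly=icer(program_cost, d_q) if d_q != 0 else math.inf,
            icer_disease_years=icer(program_cost, d_dy) if d_dy != 0 else math.inf,
            roi=roi(savings, program_cost),
        )

    weight_only = arm(effect_full.weight_only())
    full = arm(effect_full)

    return ScenarioComparison(
        effect=effect_full,
        program_cost=program_cost,
        baseline_qalys=base_q,
        baseline_disease_years=base_dy,
        weight_only=weight_only,
        full=full,
        icer_qaly_ratio=weight_only.icer_qaly / full.icer_qaly,
        icer_disease_years_ratio=weight_only.icer_disease_years / full.icer_disease_years,
        roi_ratio=weight_only.roi / full.roi,
    )


def display_round(comparison: ScenarioComparison) -> dict[str, float]:
    """Display rounding: ICERs to whole units, ratios to 3 d.p., ROI to whole %."""
    return {
        "cost": round(comparison.program_cost, 2),
        "icer_qaly_1": round(comparison.weight_only.icer_qaly),
        "icer_qaly_2": round(comparison.full.icer_qaly),
        "icer_qaly_ratio": round(comparison.icer_qaly_ratio, 3),
        "icer_dy_1": round(comparison.weight_only.icer_disease_years),
        "icer_dy_2": round(comparison.full.icer_disease_years),
        "icer_dy_ratio": round(comparison.icer_disease_years_ratio, 3),
        "roi_1": round(comparison.weight_only.roi),
        "roi_2": round(comparison.full.roi),
        "roi_ratio": round(comparison.roi_ratio, 3),
    }
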