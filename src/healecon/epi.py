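"""Epidemiological standardization and rate algebra.

Literature rate ratios are usually reported against a reference *category*
(e.g. normal weight), not against the general population.  To combine them
with life-table hazards they are re-expressed as standardized mortality
ratios (SMRs) relative to the population:

    SMR_k = MR_k / sum_k P_k * MR_k

so that the population-weighted mean SMR is exactly 1.  Under the working
assumption of no synergy or antagonism, the conditional mortality hazard for
a joint state is the life-table hazard times the product of the (standardized)
ratios over the five dimensions (weight, activity, fruit, vegetable, disease
status), and the risk-adjusted disease incidence is the published incidence
times the product of standardized relative risks over the linked factors.

Annual rates convert to per-cycle probabilities via p = 1 - exp(-rate * t).

When a disease's incidence is unavailable, it is back-calculated from two
age-specific prevalences and mortality data through a two-state illness-death
balance solved for the constant incidence by Newton-Raphson.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Union

import numpy as np

from .state_space import FACTORS


@dataclasses.dataclass(frozen=True)
class CategoryRatios:
    """Per-category rate ratios (reference = 1) with population proportions."""

    ratios: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, dtype=float)
        props = np.asarray(self.proportions, dtype=float)
        if ratios.shape != props.shape or ratios.ndim != 1:
            raise ValueError("ratios and proportions must be 1-D and the same length")
        if (ratios <= 0).any():
            raise ValueError("rate ratios must be positive")
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")
        object.__setattr__(self, "ratios", ratios)
        object.__setattr__(self, "proportions", props)


def standardize_ratios(ratios: CategoryRatios) -> np.ndarray:
    """SMR_k = MR_k / sum P_k MR_k; population-weighted mean of the result is 1."""
    mean = float(ratios.proportions @ ratios.ratios)
    return ratios.ratios / mean


def combined_hazard(
    H: float,
    dimensions: Mapping[str, CategoryRatios],
    levels: Mapping[str, int],
) -> float:
    """Conditional mortality hazard h* for one joint state.

    ``dimensions`` maps each dimension name (the four risk factors and
    ``"disease"``) to its ratios; ``levels`` gives the occupied category per
    dimension.  Each dimension contributes SMR_k / sum P SMR — division that
    is a no-op when the ratios are already standardized, so raw rate ratios
    and pre-standardized ones are both accepted.
    """
    if H < 0:
        raise ValueError("baseline hazard must be non-negative")
    h = H
    for name, level in levels.items():
        if name not in dimensions:
            raise KeyError(f"missing ratio dimension {name!r}")
        smr = standardize_ratios(dimensions[name])
        h *= smr[level]
    return h


def adjusted_incidence(
    I: float,
    factor_ratios: Mapping[str, CategoryRatios],
    profile,
    linked: tuple[str, ...] | None = None,
) -> float:
    """Risk-adjusted incidence I* for one risk profile.

    Relative risks are used only for the factors linked to the disease
    (``linked``; default: every factor present in ``factor_ratios``); each
    linked factor contributes RR_k / sum P_k RR_k, so under the population's
    factor distribution the average of I* equals I.
    """
    if I < 0:
        raise ValueError("incidence must be non-negative")
    if linked is None:
        linked = tuple(factor_ratios)
    out = I
    for factor in linked:
        if factor not in factor_ratios:
            raise KeyError(f"no relative risks supplied for linked factor {factor!r}")
        rr = standardize_ratios(factor_ratios[factor])
        out *= rr[profile.level(factor)]
    return out


def incidence_to_probability(I_star: Union[float, np.ndarray], t: float) -> Union[float, np.ndarray]:
    """Per-cycle event probability p = 1 - exp(-I* t) for annual rate I*."""
    I_star = np.asarray(I_star, dtype=float)
    if (I_star < 0).any():
        raise ValueError("incidence must be non-negative")
    if t <= 0:
        raise ValueError("cycle length must be positive")
    p = -np.expm1(-I_star * t)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Incidence back-calculation from prevalence and mortality
# ---------------------------------------------------------------------------

def _project_prevalence(
    incidence: float,
    prev_a: float,
    mort_nondiseased: float,
    mort_diseased: float,
    interval: float,
) -> float:
    """Closed-form prevalence after ``interval`` years of the illness-death ODE.

    Dynamics with constant rates: N' = -(i + m_n) N,  D' = i N - m_d D,
    starting from (N, D) = (1 - prev_a, prev_a); returns D / (N + D).
    """
    n0, d0 = 1.0 - prev_a, prev_a
    a = incidence + mort_nondiseased
    n1 = n0 * np.exp(-a * interval)
    delta = mort_diseased - a
    if abs(delta) > 1e-12:
        d1 = np.exp(-mort_diseased * interval) * d0 + incidence * n0 * (
            np.exp(-a * interval) - np.exp(-mort_diseased * interval)
        ) / delta
    else:  # degenerate: equal decay rates
        d1 = np.exp(-mort_diseased * interval) * (d0 + incidence * n0 * interval)
    return d1 / (n1 + d1)


def solve_incidence(
    prevalence_age_a: float,
    prevalence_age_b: float,
    mortality_general: float,
    mortality_ratio_diseased: float,
    interval_years: float,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Constant incidence carrying prevalence from age a to age b.

    Uses a two-state illness-death balance with differential mortality: the
    non-diseased mortality hazard is derived from the general-population
    hazard and the diseased:non-diseased mortality rate ratio at the starting
    prevalence (m = m_n * (1 - P + ratio * P)), the diseased hazard is
    ratio * m_n, and the constant incidence is solved by Newton-Raphson on the
    closed-form prevalence projection, with a bisection fallback on [0, 10].
    """
    for name, p in (("prevalence_age_a", prevalence_age_a), ("prevalence_age_b", prevalence_age_b)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if interval_years <= 0:
        raise ValueError("interval must be positive")
    if mortality_general < 0 or mortality_ratio_diseased <= 0:
        raise ValueError("mortality inputs must be positive")

    p_a = prevalence_age_a
    m_n = mortality_general / (1.0 - p_a + mortality_ratio_diseased * p_a)
    m_d = mortality_ratio_diseased * m_n

    def f(i: float) -> float:
        return _project_prevalence(i, p_a, m_n, m_d, interval_years) - prevalence_age_b

    lo, hi = 0.0, 10.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > tol:
        raise ValueError(
            f"target prevalence {prevalence_age_b} below the minimum achievable "
            f"({prevalence_age_b + f_lo:.6g}) with zero incidence"
        )
    if f_hi < -tol:
        raise ValueError("target prevalence not reachable with incidence <= 10 per year")
    if abs(f_lo) <= tol:
        return 0.0

    x = max((prevalence_age_b - p_a) / interval_years, 1e-8)  # crude start
    for _ in range(max_iter):
        fx = f(x)
        if abs(fx) < tol:
            return float(x)
        if fx > 0:
            hi = min(hi, x)
        else:
            lo = max(lo, x)
        h = max(1e-9, 1e-6 * abs(x))
        dfx = (f(x + h) - f(x - h)) / (2 * h)
        step_ok = dfx != 0
        if step_ok:
            x_new = x - fx / dfx
        if not step_ok or not (0.0 <= x_new <= 10.0):
            x_new = 0.5 * (lo + hi)  # bisection fallback
        x = x_new
    raise RuntimeError(f"incidence solver did not converge; residual {f(x):.3g}")


def per_case_cost(
    total_expenditure: float,
    category_proportion: float,
    prevalence: float,
    population: float,
) -> float:
    """Annual attributable cost per prevalent case.

    Total direct expenditure is allocated to the diagnosis category by its
    share, then divided by the number of prevalent cases.
    """
    if total_expenditure < 0 or not 0 <= category_proportion <= 1:
        raise ValueError("expenditure must be >= 0 and proportion in [0, 1]")
    cases = prevalence * population
    if cases <= 0:
        raise ValueError("no prevalent cases: prevalence * population must be positive")
    return total_expenditure * category_proportion / cases
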