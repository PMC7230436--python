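"""Parameter-directory readers/writers, run configuration and seed streams.

A parameter directory holds plain-text files:

* ``initial_distribution.csv`` — weight,activity,fruit,vegetable,probability
* ``life_table.csv`` — age,sex,hazard
* ``diseases.csv`` — id,name,mortality_ratio,prevalence,utility_decrement,annual_cost
* ``relative_risks.csv`` — disease,factor,category,rr
* ``incidence.csv`` — disease,sex,age,incidence
* ``mortality_ratios.csv`` — factor,category,ratio
* ``risk_proportions.csv`` — factor,category,proportion
* ``transition_model.json`` — term-name -> coefficient (and optional SEs)
* ``settings.json`` — decrements, discounting, horizon, cycle, sex mix

All randomness in the package flows from one top-level seed split into named
streams, so independent stages (fixtures, panel simulation, PSA) can be
reproduced in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import AgeRateCurve, DiseaseSpec, LifeTable, ModelParameters, SEXES
from .outcomes import ScenarioComparison, display_round
from .program_effects import JointRiskDistribution, ProgramEffect
from .psa import PSAResult
from .state_space import FACTORS, FACTOR_LEVELS, N_DISEASES, RiskProfile
from .transitions import TransitionCoefficients


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible random stream derived from the top-level seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclasses.dataclass
class RunConfig:
    """Run-level settings shared by the CLI commands."""

    params_dir: str = "params"
    out_dir: str = "results"
    horizon_years: int = 84
    cycle_years: int = 1
    discount_rate: float = 0.015
    sex_mix: float = 0.5
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.horizon_years % self.cycle_years:
            raise ValueError("horizon must be a multiple of the cycle length")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_parameters(params: ModelParameters, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, p in enumerate(params.initial.as_array()):
        prof = RiskProfile.from_index(i)
        rows.append((prof.weight, prof.activity, prof.fruit, prof.vegetable, p))
    pd.DataFrame(rows, columns=["weight", "activity", "fruit", "vegetable", "probability"]).to_csv(
        directory / "initial_distribution.csv", index=False
    )

    lt = params.life_table
    pd.DataFrame(
        [(a, sex, h) for sex in SEXES for a, h in zip(lt.ages, lt.hazards[sex])],
        columns=["age", "sex", "hazard"],
    ).to_csv(directory / "life_table.csv", index=False)

    pd.DataFrame(
        [
            (d.disease_id, d.name, d.mortality_ratio, d.prevalence, d.utility_decrement, d.annual_cost)
            for d in params.diseases
        ],
        columns=["id", "name", "mortality_ratio", "prevalence", "utility_decrement", "annual_cost"],
    ).to_csv(directory / "diseases.csv", index=False)

    rr_rows = [
        (d.disease_id, factor, k, rr[k])
        for d in params.diseases
        for factor, rr in d.relative_risks.items()
        for k in range(len(rr))
    ]
    pd.DataFrame(rr_rows, columns=["disease", "factor", "category", "rr"]).to_csv(
        directory / "relative_risks.csv", index=False
    )

    inc_rows = [
        (d.disease_id, sex, a, v)
        for d in params.diseases
        for sex in SEXES
        for a, v in zip(d.incidence.ages, d.incidence.values[sex])
    ]
    pd.DataFrame(inc_rows, columns=["disease", "sex", "age", "incidence"]).to_csv(
        directory / "incidence.csv", index=False
    )

    pd.DataFrame(
        [(f, k, v) for f in FACTORS for k, v in enumerate(params.mortality_rate_ratios[f])],
        columns=["factor", "category", "ratio"],
    ).to_csv(directory / "mortality_ratios.csv", index=False)

    pd.DataFrame(
        [(f, k, v) for f in FACTORS for k, v in enumerate(params.risk_proportions[f])],
        columns=["factor", "category", "proportion"],
    ).to_csv(directory / "risk_proportions.csv", index=False)

    with open(directory / "transition_model.json", "w") as fh:
        json.dump(params.coefficients.to_dict(), fh, indent=1)

    settings = {
        "overweight_decrement": params.weight_decrements[0],
        "obese_decrement": params.weight_decrements[1],
        "discount_rate": params.discount_rate,
        "horizon_years": params.horizon_years,
        "cycle_years": params.cycle_years,
        "start_age": params.start_age,
        "sex_mix": params.sex_mix,
    }
    with open(directory / "settings.json", "w") as fh:
        json.dump(settings, fh, indent=1)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing parameter file: {path}")
    return path


def load_parameters(directory) -> ModelParameters:
    """Load and fully validate a parameter directory.

    Invariant violations (probabilities off the simplex, wrong disease count,
    non-positive ratios, ...) surface as exceptions naming the offending file.
    """
    directory = Path(directory)

    df = pd.read_csv(_require(directory / "initial_distribution.csv"))
    probs = np.zeros(24)
    for _, row in df.iterrows():
        prof = RiskProfile(int(row.weight), int(row.activity), int(row.fruit), int(row.vegetable))
        probs[prof.index] = row.probability
    try:
        initial = JointRiskDistribution(probs)
    except ValueError as exc:
        raise ValueError(f"initial_distribution.csv: {exc}") from exc

    df = pd.read_csv(_require(directory / "life_table.csv"))
    ages = np.sort(df["age"].unique()).astype(float)
    hazards = {}
    for sex in SEXES:
        sub = df[df.sex == sex].sort_values("age")
        if not np.array_equal(sub["age"].to_numpy(dtype=float), ages):
            raise ValueError(f"life_table.csv: age grid differs between sexes ({sex})")
        hazards[sex] = sub["hazard"].to_numpy(dtype=float)
    life_table = LifeTable(ages, hazards)

    dis = pd.read_csv(_require(directory / "diseases.csv")).sort_values("id")
    rr = pd.read_csv(_require(directory / "relative_risks.csv"))
    inc = pd.read_csv(_require(directory / "incidence.csv"))
    diseases = []
    for _, row in dis.iterrows():
        d = int(row["id"])
        rrs = {}
        for factor in FACTORS:
            sub = rr[(rr.disease == d) & (rr.factor == factor)].sort_values("category")
            if len(sub):
                rrs[factor] = sub["rr"].to_numpy(dtype=float)
        curve_values = {}
        grid = None
        for sex in SEXES:
            sub = inc[(inc.disease == d) & (inc.sex == sex)].sort_values("age")
            if not len(sub):
                raise ValueError(f"incidence.csv: no rows for disease {d}, sex {sex}")
            grid = sub["age"].to_numpy(dtype=float)
            curve_values[sex] = sub["incidence"].to_numpy(dtype=float)
        try:
            diseases.append(
                DiseaseSpec(
                    disease_id=d,
                    name=str(row["name"]),
                    relative_risks=rrs,
                    incidence=AgeRateCurve(grid, curve_values),
                    mortality_ratio=float(row["mortality_ratio"]),
                    prevalence=float(row["prevalence"]),
                    utility_decrement=float(row["utility_decrement"]),
                    annual_cost=float(row["annual_cost"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"diseases.csv id {d}: {exc}") from exc

    mr = pd.read_csv(_require(directory / "mortality_ratios.csv"))
    rp = pd.read_csv(_require(directory / "risk_proportions.csv"))
    mortality_ratios, proportions = {}, {}
    for factor in FACTORS:
        sub = mr[mr.factor == factor].sort_values("category")
        mortality_ratios[factor] = sub["ratio"].to_numpy(dtype=float)
        sub = rp[rp.factor == factor].sort_values("category")
        proportions[factor] = sub["proportion"].to_numpy(dtype=float)

    with open(_require(directory / "transition_model.json")) as fh:
        coefficients = TransitionCoefficients.from_dict(json.load(fh))

    with open(_require(directory / "settings.json")) as fh:
        settings = json.load(fh)

    return ModelParameters(
        initial=initial,
        coefficients=coefficients,
        diseases=diseases,
        life_table=life_table,
        mortality_rate_ratios=mortality_ratios,
        risk_proportions=proportions,
        weight_decrements=(settings["overweight_decrement"], settings["obese_decrement"]),
        discount_rate=settings["discount_rate"],
        horizon_years=settings["horizon_years"],
        cycle_years=settings["cycle_years"],
        start_age=settings["start_age"],
        sex_mix=settings["sex_mix"],
    )


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def comparison_row(comparison: ScenarioComparison) -> dict:
    """One table row in the conventional column order: effect odds ratios,
    cost, incremental effects, ICERs and ratios."""
    e = comparison.effect
    rounded = display_round(comparison)
    return {
        "alpha1": e.overweight_or,
        "alpha2": e.obesity_or,
        "psi1": e.activity_or,
        "lambda1": e.fruit_or,
        "tau1": e.vegetable_or,
        "cost": rounded["cost"],
        "effect_qaly_1": round(comparison.weight_only.incremental_qalys, 4),
        "icer_qaly_1": rounded["icer_qaly_1"],
        "effect_qaly_2": round(comparison.full.incremental_qalys, 4),
        "icer_qaly_2": rounded["icer_qaly_2"],
        "icer_qaly_ratio": rounded["icer_qaly_ratio"],
        "effect_dy_1": round(comparison.weight_only.incremental_disease_years, 5),
        "icer_dy_1": rounded["icer_dy_1"],
        "effect_dy_2": round(comparison.full.incremental_disease_years, 5),
        "icer_dy_2": rounded["icer_dy_2"],
        "icer_dy_ratio": rounded["icer_dy_ratio"],
        "savings_1": round(comparison.weight_only.savings, 3),
        "roi_1": rounded["roi_1"],
        "savings_2": round(comparison.full.savings, 3),
        "roi_2": rounded["roi_2"],
        "roi_ratio": rounded["roi_ratio"],
    }


def write_results(
    comparisons: list[ScenarioComparison],
    directory,
    seed: int | None = None,
    discount_rate: float = 0.015,
    psa: PSAResult | None = None,
) -> None:
    """Write the comparison table(s) as CSV plus an unrounded JSON with metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([comparison_row(c) for c in comparisons])
    table.to_csv(directory / "comparison.csv", index=False)

    raw = []
    for c in comparisons:
        raw.append(
            {
                "effect": c.effect.to_dict(),
                "program_cost": c.program_cost,
                "baseline_qalys": c.baseline_qalys,
                "baseline_disease_years": c.baseline_disease_years,
                "weight_only": dataclasses.asdict(c.weight_only),
                "full": dataclasses.asdict(c.full),
                "icer_qaly_ratio": c.icer_qaly_ratio,
                "icer_disease_years_ratio": c.icer_disease_years_ratio,
                "roi_ratio": c.roi_ratio,
            }
        )
    payload = {
        "results": raw,
        "metadata": {
            "seed": seed,
            "discount_rate": discount_rate,
            "config_hash": _config_hash(raw),
        },
    }
    if psa is not None:
        payload["psa"] = {
            name: dataclasses.asdict(s) for name, s in psa.summaries.items()
        }
        payload["psa_failures"] = psa.n_failures
    with open(directory / "results.json", "w") as fh:
        json.dump(payload, fh, indent=1)
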