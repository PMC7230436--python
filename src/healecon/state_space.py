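"""Markov state space for the multi-risk-factor chronic-disease model.

The model tracks four behavioural/weight risk factors jointly:

* weight status — 0 normal weight, 1 overweight, 2 obese
* physical activity — 0 not meeting / 1 meeting recommendations
* fruit consumption — 0 not meeting / 1 meeting recommendations
* vegetable consumption — 0 not meeting / 1 meeting recommendations

giving 3 x 2 x 2 x 2 = 24 joint risk profiles.  Crossing these with 33
chronic-disease statuses (no chronic disease plus 32 diseases with
established risk-factor links) and adding an absorbing Dead state yields
24 x 33 + 1 = 793 Markov states.

Enumeration order (fixed, documented, used by every trace and test):
disease-major, then weight, activity, fruit, vegetable lexicographically;
the Dead state is last (index 792).
"""
from __future__ import annotations

import dataclasses
import importlib.resources
import re
from typing import Iterable, Union

import numpy as np
import pandas as pd

FACTORS = ("weight", "activity", "fruit", "vegetable")
FACTOR_LEVELS = {"weight": 3, "activity": 2, "fruit": 2, "vegetable": 2}

N_PROFILES = 24
N_DISEASES = 32
N_DISEASE_STATUS = 33  # 0 = no chronic disease
N_STATES = N_PROFILES * N_DISEASE_STATUS + 1  # 793
DEAD_INDEX = N_STATES - 1


@dataclasses.dataclass(frozen=True, order=True)
class RiskProfile:
    """One joint classification of the four risk factors."""

    weight: int
    activity: int
    fruit: int
    vegetable: int

    def __post_init__(self) -> None:
        for factor in FACTORS:
            level = getattr(self, factor)
            if not 0 <= level < FACTOR_LEVELS[factor]:
                raise ValueError(
                    f"{factor} level {level} outside 0..{FACTOR_LEVELS[factor] - 1}"
                )

    @property
    def index(self) -> int:
        """Position in the fixed lexicographic enumeration (0..23)."""
        return ((self.weight * 2 + self.activity) * 2 + self.fruit) * 2 + self.vegetable

    @classmethod
    def from_index(cls, index: int) -> "RiskProfile":
        if not 0 <= index < N_PROFILES:
            raise ValueError(f"profile index {index} outside 0..{N_PROFILES - 1}")
        v = index % 2
        f = (index // 2) % 2
        p = (index // 4) % 2
        w = index // 8
        return cls(w, p, f, v)

    def level(self, factor: str) -> int:
        return getattr(self, factor)


def enumerate_profiles() -> list[RiskProfile]:
    """All 24 risk profiles in index order."""
    return [RiskProfile.from_index(i) for i in range(N_PROFILES)]


@dataclasses.dataclass(frozen=True)
class DiseaseStatus:
    """Chronic-disease status: 0 = none, 1..32 = one specific disease."""

    id: int

    def __post_init__(self) -> None:
        if not 0 <= self.id < N_DISEASE_STATUS:
            raise ValueError(f"disease id {self.id} outside 0..{N_DISEASE_STATUS - 1}")


@dataclasses.dataclass(frozen=True)
class MarkovState:
    """Alive(profile, disease) or the absorbing Dead state."""

    profile: RiskProfile | None = None
    disease: int | None = None

    def __post_init__(self) -> None:
        if (self.profile is None) != (self.disease is None):
            raise ValueError("profile and disease must both be set, or both be None")
        if self.disease is not None and not 0 <= self.disease < N_DISEASE_STATUS:
            raise ValueError(f"disease id {self.disease} outside 0..{N_DISEASE_STATUS - 1}")

    @property
    def dead(self) -> bool:
        return self.profile is None


DEAD = MarkovState()


def build_state_space() -> list[MarkovState]:
    """The 793 Markov states in the fixed enumeration order, Dead last."""
    states = [
        MarkovState(profile, disease)
        for disease in range(N_DISEASE_STATUS)
        for profile in enumerate_profiles()
    ]
    states.append(DEAD)
    return states


def state_index(state: MarkovState) -> int:
    """Inverse of the :func:`build_state_space` enumeration."""
    if state.dead:
        return DEAD_INDEX
    return state.disease * N_PROFILES + state.profile.index


def state_at(index: int) -> MarkovState:
    if not 0 <= index < N_STATES:
        raise ValueError(f"state index {index} outside 0..{N_STATES - 1}")
    if index == DEAD_INDEX:
        return DEAD
    disease, profile = divmod(index, N_PROFILES)
    return MarkovState(RiskProfile.from_index(profile), disease)


def canonical_disease_name(name: str) -> str:
    """Case-insensitive, whitespace- and apostrophe-normalized disease name."""
    name = name.replace("’", "'").strip().lower()
    return re.sub(r"\s+", " ", name)


class LinkageMatrix:
    """Which of the four risk factors carry a significant relative risk per disease.

    Rows are the 32 chronic diseases in their canonical order (ids 1..32);
    columns are the four risk factors.  Entry 1 means the disease's incidence
    is modelled as depending on that factor.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ("disease", *FACTORS) if c not in table.columns]
        if missing:
            raise ValueError(f"linkage table missing columns {missing}")
        if len(table) != N_DISEASES:
            raise ValueError(f"linkage table has {len(table)} rows, expected {N_DISEASES}")
        table = table.reset_index(drop=True)
        values = table[list(FACTORS)].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("linkage indicators must be 0/1")
        self.names: list[str] = [str(n).strip() for n in table["disease"]]
        self._canon = {canonical_disease_name(n): i for i, n in enumerate(self.names)}
        if len(self._canon) != N_DISEASES:
            raise ValueError("duplicate disease names in linkage table")
        self.indicator: np.ndarray = values.astype(bool)

    def disease_id(self, name: str) -> int:
        """1-based disease id for a (canonicalized) disease name."""
        key = canonical_disease_name(name)
        if key not in self._canon:
            raise KeyError(f"unknown disease name: {name!r}")
        return self._canon[key] + 1

    def linked(self, disease: Union[str, int]) -> tuple[str, ...]:
        """Factors linked to a disease, given by name or 1-based id."""
        if isinstance(disease, str):
            row = self.disease_id(disease) - 1
        else:
            if not 1 <= disease <= N_DISEASES:
                raise ValueError(f"disease id {disease} outside 1..{N_DISEASES}")
            row = disease - 1
        return tuple(f for f, on in zip(FACTORS, self.indicator[row]) if on)

    def is_linked(self, disease_id: int, factor: str) -> bool:
        return self.indicator[disease_id - 1, FACTORS.index(factor)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"disease": self.names, **{f: self.indicator[:, i].astype(int) for i, f in enumerate(FACTORS)}}
        )


def load_linkage(source: Union[str, pd.DataFrame, None] = None) -> LinkageMatrix:
    """Load the disease/risk-factor linkage table.

    With no argument, the packaged table of the 32 chronic diseases with
    Global-Burden-of-Disease-supported risk-factor links is used.
    """
    if source is None:
        ref = importlib.resources.files("healecon") / "data" / "disease_linkage.csv"
        with importlib.resources.as_file(ref) as path:
            table = pd.read_csv(path)
    elif isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source)
    return LinkageMatrix(table)
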