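"""Program effects on the joint risk-factor distribution.

A health-promotion program is summarized by odds ratios per risk-factor
category (reference category fixed at odds ratio 1).  Applying the effect of
one factor multiplies, within every stratum of the other three factors, each
cell's probability by its odds multiplier and renormalizes so the stratum
keeps its total mass — i.e. the conditional odds of each category given the
other factors are multiplied by the stated odds ratio while the joint
distribution of the remaining factors is untouched.  The full program effect
is the sequential composition over the four factors.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .state_space import FACTORS, FACTOR_LEVELS, N_PROFILES

SHAPE = tuple(FACTOR_LEVELS[f] for f in FACTORS)  # (3, 2, 2, 2)
DEFAULT_ORDER = FACTORS  # weight -> activity -> fruit -> vegetable

_SUM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class JointRiskDistribution:
    """Probability over the 24 joint risk profiles, in profile-index order."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float).reshape(-1)
        if probs.size != N_PROFILES:
            raise ValueError(f"expected {N_PROFILES} probabilities, got {probs.size}")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {probs.sum():.12g}, not 1")
        object.__setattr__(self, "probs", probs)

    def as_array(self) -> np.ndarray:
        """Flat copy in profile-index order."""
        return self.probs.copy()

    def as_grid(self) -> np.ndarray:
        """View shaped (weight, activity, fruit, vegetable)."""
        return self.probs.reshape(SHAPE)

    def marginal(self, factor: str) -> np.ndarray:
        axis = FACTORS.index(factor)
        other = tuple(i for i in range(4) if i != axis)
        return self.as_grid().sum(axis=other)

    @classmethod
    def uniform(cls) -> "JointRiskDistribution":
        return cls(np.full(N_PROFILES, 1.0 / N_PROFILES))


@dataclasses.dataclass(frozen=True)
class ProgramEffect:
    """Odds multipliers xi per risk-factor category; reference category = 1.

    Conventional symbols: weight (alpha_0=1, alpha_1 overweight, alpha_2 obese),
    activity psi_1, fruit lambda_1, vegetable tau_1.
    """

    overweight_or: float = 1.0
    obesity_or: float = 1.0
    activity_or: float = 1.0
    fruit_or: float = 1.0
    vegetable_or: float = 1.0

    def __post_init__(self) -> None:
        for name in ("overweight_or", "obesity_or", "activity_or", "fruit_or", "vegetable_or"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def multipliers(self, factor: str) -> np.ndarray:
        if factor == "weight":
            return np.array([1.0, self.overweight_or, self.obesity_or])
        if factor == "activity":
            return np.array([1.0, self.activity_or])
        if factor == "fruit":
            return np.array([1.0, self.fruit_or])
        if factor == "vegetable":
            return np.array([1.0, self.vegetable_or])
        raise KeyError(f"unknown factor {factor!r}")

    @property
    def is_null(self) -> bool:
        return all(
            getattr(self, n) == 1.0
            for n in ("overweight_or", "obesity_or", "activity_or", "fruit_or", "vegetable_or")
        )

    def weight_only(self) -> "ProgramEffect":
        """Same weight-status effect with all behavioural odds ratios at 1."""
        return ProgramEffect(overweight_or=self.overweight_or, obesity_or=self.obesity_or)

    def to_dict(self) -> dict[str, float]:
        return {
            "overweight_or": self.overweight_or,
            "obesity_or": self.obesity_or,
            "activity_or": self.activity_or,
            "fruit_or": self.fruit_or,
            "vegetable_or": self.vegetable_or,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ProgramEffect":
        known = {"overweight_or", "obesity_or", "activity_or", "fruit_or", "vegetable_or"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown program-effect keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def null(cls) -> "ProgramEffect":
        return cls()


def apply_factor_effect(
    dist: JointRiskDistribution, factor: str, multipliers: Sequence[float]
) -> JointRiskDistribution:
    """Scale one factor's categories by their odds multipliers, stratum by stratum.

    Within every combination of the other three factors the cell masses are
    multiplied by the category's odds multiplier and renormalized to the
    stratum's original total, so the marginal distribution over the other
    factors is preserved exactly.  Zero-mass strata pass through unchanged.
    """
    axis = FACTORS.index(factor)
    xi = np.asarray(multipliers, dtype=float)
    if xi.size != FACTOR_LEVELS[factor]:
        raise ValueError(
            f"{factor} needs {FACTOR_LEVELS[factor]} multipliers, got {xi.size}"
        )
    if (xi <= 0).any():
        raise ValueError("odds multipliers must be positive")

    theta = dist.as_grid().copy()
    shape = [1, 1, 1, 1]
    shape[axis] = xi.size
    weighted = theta * xi.reshape(shape)
    stratum_mass = theta.sum(axis=axis, keepdims=True)
    weighted_mass = weighted.sum(axis=axis, keepdims=True)
    # zero-mass strata: keep original (zero) cells, avoid 0/0; the ratio is
    # formed first so unit multipliers reproduce the input bitwise
    safe = np.where(weighted_mass > 0, weighted_mass, 1.0)
    out = np.where(stratum_mass > 0, weighted * (stratum_mass / safe), theta)
    return JointRiskDistribution(out.reshape(-1))


def apply_program_effect(
    dist: JointRiskDistribution,
    effect: ProgramEffect,
    order: Sequence[str] = DEFAULT_ORDER,
) -> JointRiskDistribution:
    """Compose the per-factor effects in the given order (default documented).

    The composite is not guaranteed order-invariant in general, hence the
    explicit, fixed default order weight -> activity -> fruit -> vegetable.
    """
    if sorted(order) != sorted(FACTORS):
        raise ValueError(f"order must be a permutation of {FACTORS}")
    out = dist
    for factor in order:
        out = apply_factor_effect(out, factor, effect.multipliers(factor))
    return out
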