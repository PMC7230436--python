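"""Joint multinomial-logit model of two-year risk-factor transitions.

The 24 joint risk profiles at the next assessment (two years later) are
modelled as a single multinomial outcome whose linear predictor is built from
*outcome-component dummies* — w1, w2 (overweight/obese next), p1, f1, v1
(meeting activity/fruit/vegetable recommendations next) — each of which can
be crossed with covariates (sex, age, and the current status dummies) and
with each other (two- and three-way associations between the outcome
components, which is what makes the model *joint* rather than four
independent logits).  The profile with all components at their reference
level has linear predictor 0.

A term is a product of outcome dummies times at most one covariate; the
model is therefore described by a term list (the interaction structure) and
one coefficient per term:

    eta(c | x) = sum_j beta_j * g_j(c) * x_j,
    P(c | x) = exp(eta_c) / sum_c' exp(eta_c')

where g_j(c) is the product of the term's outcome dummies evaluated at
category c and x_j is the term's covariate value (1 for intercept terms).

Fitting maximizes the exact multinomial log-likelihood (quasi-Newton with
analytic gradient, optional L2 ridge for separation); standard errors come
from the inverse observed information.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import logsumexp, softmax

from .state_space import N_PROFILES, RiskProfile, enumerate_profiles

OUTCOME_DUMMIES = ("w1", "w2", "p1", "f1", "v1")
COVARIATES = ("sex", "age", "cw1", "cw2", "cp1", "cf1", "cv1")
_FACTOR_DUMMIES = {"w": ("w1", "w2"), "p": ("p1",), "f": ("f1",), "v": ("v1",)}

# Age enters the linear predictor on a centered/scaled axis so that
# coefficients are O(1) over the adult age range.
AGE_CENTER = 50.0
AGE_SCALE = 50.0


def _age_covariate(age) -> np.ndarray:
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


@dataclasses.dataclass(frozen=True)
class Term:
    """One model term: a product of outcome dummies times at most one covariate."""

    outcomes: tuple[str, ...]
    covariate: str | None = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("a term needs at least one outcome dummy")
        for o in self.outcomes:
            if o not in OUTCOME_DUMMIES:
                raise ValueError(f"unknown outcome dummy {o!r}")
        if self.covariate is not None and self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    @property
    def name(self) -> str:
        base = "*".join(self.outcomes)
        return base if self.covariate is None else f"{base}:{self.covariate}"

    @classmethod
    def from_name(cls, name: str) -> "Term":
        base, _, cov = name.partition(":")
        return cls(tuple(base.split("*")), cov or None)


def default_structure() -> tuple[Term, ...]:
    """Main effects of each outcome component (with all covariates) plus
    two- and three-way associations between the outcome components."""
    terms: list[Term] = []
    for o in OUTCOME_DUMMIES:
        terms.append(Term((o,)))
        terms.extend(Term((o,), cov) for cov in COVARIATES)
    for k in (2, 3):
        for combo in itertools.combinations("wpfv", k):
            for dummies in itertools.product(*(_FACTOR_DUMMIES[c] for c in combo)):
                terms.append(Term(tuple(dummies)))
    return tuple(terms)


def _category_dummies() -> np.ndarray:
    """(24, 5) matrix of outcome-dummy values per profile category."""
    rows = []
    for prof in enumerate_profiles():
        rows.append(
            [
                prof.weight == 1,
                prof.weight == 2,
                prof.activity == 1,
                prof.fruit == 1,
                prof.vegetable == 1,
            ]
        )
    return np.array(rows, dtype=float)


def category_matrix(terms: Sequence[Term]) -> np.ndarray:
    """G with G[c, j] = product of term j's outcome dummies at category c."""
    dummies = _category_dummies()
    cols = []
    for term in terms:
        g = np.ones(N_PROFILES)
        for o in term.outcomes:
            g = g * dummies[:, OUTCOME_DUMMIES.index(o)]
        cols.append(g)
    return np.column_stack(cols)


def covariate_matrix(terms: Sequence[Term], sex, age, current_index) -> np.ndarray:
    """X with X[i, j] = covariate value of term j for observation i."""
    sex = np.atleast_1d(np.asarray(sex, dtype=float))
    age_c = np.atleast_1d(_age_covariate(age))
    cur = np.atleast_1d(np.asarray(current_index, dtype=int))
    n = max(sex.size, age_c.size, cur.size)
    sex, age_c, cur = (np.broadcast_to(a, n) for a in (sex, age_c, cur))
    dummies = _category_dummies()[cur]  # (n, 5) current-status dummies
    values = {
        "sex": sex,
        "age": age_c,
        "cw1": dummies[:, 0],
        "cw2": dummies[:, 1],
        "cp1": dummies[:, 2],
        "cf1": dummies[:, 3],
        "cv1": dummies[:, 4],
    }
    cols = [np.ones(n) if t.covariate is None else values[t.covariate] for t in terms]
    return np.column_stack(cols)


@dataclasses.dataclass
class TransitionCoefficients:
    """Fitted (or specified) coefficients of the joint transition model."""

    terms: tuple[Term, ...]
    values: np.ndarray
    se: np.ndarray | None = None
    loglik: float | None = None
    converged: bool = True
    grad_norm: float | None = None

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.terms),):
            raise ValueError("one coefficient required per term")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se shape must match values")
        self._G = category_matrix(self.terms)

    @property
    def G(self) -> np.ndarray:
        return self._G

    @classmethod
    def null(cls, terms: Sequence[Term] | None = None) -> "TransitionCoefficients":
        terms = tuple(terms) if terms is not None else default_structure()
        return cls(terms, np.zeros(len(terms)))

    def to_dict(self) -> dict:
        out = {"coef": {t.name: float(v) for t, v in zip(self.terms, self.values)}}
        if self.se is not None:
            out["se"] = {t.name: float(s) for t, s in zip(self.terms, self.se)}
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "TransitionCoefficients":
        terms = tuple(Term.from_name(n) for n in data["coef"])
        values = np.array([data["coef"][t.name] for t in terms])
        se = None
        if data.get("se"):
            se = np.array([data["se"][t.name] for t in terms])
        return cls(terms, values, se)


def transition_probabilities(
    coef: TransitionCoefficients, sex: int, age: float, current: RiskProfile
) -> np.ndarray:
    """Probability over the 24 next-period profiles for one covariate pattern."""
    X = covariate_matrix(coef.terms, sex, age, current.index)  # (1, K)
    eta = (X * coef.values) @ coef.G.T  # (1, 24)
    return softmax(eta[0])


def _two_year_matrix(coef: TransitionCoefficients, sex: int, age: float) -> np.ndarray:
    X = covariate_matrix(coef.terms, sex, age, np.arange(N_PROFILES))  # (24, K)
    eta = (X * coef.values) @ coef.G.T
    return softmax(eta, axis=1)


def per_cycle_matrix(
    coef: TransitionCoefficients,
    sex: int,
    age: float,
    cycle_years: int,
    root_tol: float = 1e-6,
) -> np.ndarray:
    """Row-stochastic transition matrix for one Markov cycle.

    The model estimates two-year transitions; a one-year cycle uses the
    principal matrix square root projected to the nearest valid stochastic
    matrix (negative entries clipped, rows renormalized).  A two-year
    probability matrix is not guaranteed embeddable, so the squared root may
    deviate from the original; large deviations raise.
    """
    if cycle_years not in (1, 2):
        raise ValueError("cycle_years must be 1 or 2")
    M = _two_year_matrix(coef, sex, age)
    if cycle_years == 2:
        return M
    root = scipy.linalg.sqrtm(M)
    root = np.real_if_close(root, tol=1e6)
    root = np.real(root)
    root = np.clip(root, 0.0, None)
    sums = root.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise RuntimeError("matrix square root projection produced an empty row")
    root /= sums
    if np.linalg.norm(root @ root - M, "fro") > max(root_tol, 1e-3):
        raise RuntimeError("annualized matrix deviates strongly from the 2-year model")
    return root


def simulate_panel(
    coef: TransitionCoefficients,
    n: int,
    waves: int = 1,
    seed: int | np.random.Generator = 0,
    age_range: tuple[float, float] = (12.0, 70.0),
    initial: np.ndarray | None = None,
    male_fraction: float = 0.5,
) -> pd.DataFrame:
    """Simulate two-year panel transitions from the model.

    Returns one row per observed transition with columns
    ``subject,sex,age,w0,p0,f0,v0,w1,p1,f1,v1`` (sex: 0 female, 1 male; age at
    the start of the transition).  Reproducible for a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sex = (rng.random(n) < male_fraction).astype(int)
    age = rng.uniform(age_range[0], age_range[1], n)
    if initial is None:
        current = rng.integers(0, N_PROFILES, n)
    else:
        initial = np.asarray(initial, dtype=float)
        current = rng.choice(N_PROFILES, size=n, p=initial / initial.sum())

    profiles = enumerate_profiles()
    levels = np.array([[p.weight, p.activity, p.fruit, p.vegetable] for p in profiles])
    records = []
    for wave in range(waves):
        X = covariate_matrix(coef.terms, sex, age, current)
        eta = (X * coef.values) @ coef.G.T
        P = softmax(eta, axis=1)
        u = rng.random(n)
        nxt = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        frame = pd.DataFrame(
            {
                "subject": np.arange(n),
                "sex": sex,
                "age": age,
                "w0": levels[current, 0],
                "p0": levels[current, 1],
                "f0": levels[current, 2],
                "v0": levels[current, 3],
                "w1": levels[nxt, 0],
                "p1": levels[nxt, 1],
                "f1": levels[nxt, 2],
                "v1": levels[nxt, 3],
            }
        )
        records.append(frame)
        current = nxt
        age = age + 2.0
    return pd.concat(records, ignore_index=True)


def _panel_arrays(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    cur = ((data["w0"].to_numpy() * 2 + data["p0"].to_numpy()) * 2 + data["f0"].to_numpy()) * 2 + data[
        "v0"
    ].to_numpy()
    nxt = ((data["w1"].to_numpy() * 2 + data["p1"].to_numpy()) * 2 + data["f1"].to_numpy()) * 2 + data[
        "v1"
    ].to_numpy()
    return (
        data["sex"].to_numpy(dtype=float),
        data["age"].to_numpy(dtype=float),
        cur.astype(int),
        nxt.astype(int),
    )


def fit_joint_logit(
    data: pd.DataFrame,
    structure: Sequence[Term] | None = None,
    ridge: float = 0.0,
    max_iter: int = 2000,
    gtol: float = 1e-8,
) -> TransitionCoefficients:
    """Maximum-likelihood fit of the joint transition model.

    ``data`` holds one transition per row (see :func:`simulate_panel` for the
    column layout).  ``structure`` is the term list (default:
    :func:`default_structure`).  ``ridge`` adds an L2 penalty, useful under
    quasi-separation.  Raises on non-convergence with the residual gradient
    norm in the message.
    """
    terms = tuple(structure) if structure is not None else default_structure()
    sex, age, cur, nxt = _panel_arrays(data)
    n = len(nxt)
    if n == 0:
        raise ValueError("empty panel")
    G = category_matrix(terms)
    X = covariate_matrix(terms, sex, age, cur)
    Gy = G[nxt]  # (n, K)

    def objective(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = (X * beta) @ G.T  # (n, 24)
        lse = logsumexp(eta, axis=1)
        ll = float((eta[np.arange(n), nxt] - lse).sum())
        P = softmax(eta, axis=1)
        grad = (((P @ G) - Gy) * X).sum(axis=0)
        nll = -ll / n + 0.5 * ridge * float(beta @ beta)
        return nll, grad / n + ridge * beta

    beta0 = np.zeros(len(terms))
    history: list[float] = []

    def cb(beta: np.ndarray) -> None:
        history.append(objective(beta)[0])

    res = scipy.optimize.minimize(
        objective,
        beta0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
    )
    beta = res.x
    grad_norm = float(np.linalg.norm(objective(beta)[1], np.inf))
    if grad_norm > 1e-6:
        raise RuntimeError(
            f"joint logit fit did not converge: max|grad| = {grad_norm:.3g} "
            f"({res.message}); consider a ridge penalty if the data are separated"
        )

    # observed information of the total (unscaled) log-likelihood
    eta = (X * beta) @ G.T
    P = softmax(eta, axis=1)
    A = P @ G  # (n, K)
    U = X * A
    H = -(U.T @ U)
    for c in range(N_PROFILES):
        V = X * G[c]
        H += V.T @ (P[:, c : c + 1] * V)
    H += n * ridge * np.eye(len(terms))
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(terms), np.nan)

    eta_ll = float((eta[np.arange(n), nxt] - logsumexp(eta, axis=1)).sum())
    return TransitionCoefficients(
        terms, beta, se=se, loglik=eta_ll, converged=True, grad_norm=grad_norm
    )


def null_loglik(data: pd.DataFrame) -> float:
    """Log-likelihood of the all-zero-coefficient (uniform) model."""
    return -len(data) * float(np.log(N_PROFILES))
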