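import numpy as np
import pytest

import healecon as h
from healecon.state_space import enumerate_profiles
from healecon.transitions import (
    AGE_CENTER,
    AGE_SCALE,
    Term,
    default_structure,
    null_loglik,
)


def _small_structure():
    return (
        Term(("w1",)), Term(("w2",)), Term(("p1",)), Term(("f1",)), Term(("v1",)),
        Term(("w1",), "cw1"), Term(("w2",), "cw2"), Term(("p1",), "cp1"),
        Term(("f1",), "cf1"), Term(("v1",), "cv1"),
        Term(("p1",), "age"), Term(("w2", "p1")),
    )


def _brute_force_probs(coef, sex, age, current):
    """Independent enumeration of exp(linear predictor)/sum over the 24 categories."""
    age_c = (age - AGE_CENTER) / AGE_SCALE
    cov = {
        "sex": sex, "age": age_c,
        "cw1": float(current.weight == 1), "cw2": float(current.weight == 2),
        "cp1": float(current.activity), "cf1": float(current.fruit),
        "cv1": float(current.vegetable), None: 1.0,
    }
    etas = []
    for prof in enumerate_profiles():
        dummy = {"w1": float(prof.weight == 1), "w2": float(prof.weight == 2),
                 "p1": float(prof.activity), "f1": float(prof.fruit),
                 "v1": float(prof.vegetable)}
        eta = 0.0
        for term, beta in zip(coef.terms, coef.values):
            g = 1.0
            for o in term.outcomes:
                g *= dummy[o]
            eta += beta * g * cov[term.covariate]
        etas.append(eta)
    e = np.exp(np.array(etas))
    return e / e.sum()


def test_null_model_is_uniform():
    coef = h.TransitionCoefficients.null()
    p = h.transition_probabilities(coef, 0, 30.0, h.RiskProfile(0, 0, 0, 0))
    np.testing.assert_allclose(p, np.full(24, 1 / 24), atol=1e-14)


def test_probabilities_match_enumeration_oracle():
    rng = np.random.default_rng(5)
    terms = _small_structure()
    coef = h.TransitionCoefficients(terms, rng.normal(0, 0.8, len(terms)))
    for current in (h.RiskProfile(0, 0, 0, 0), h.RiskProfile(2, 1, 0, 1)):
        for sex, age in ((0, 25.0), (1, 67.0)):
            p = h.transition_probabilities(coef, sex, age, current)
            np.testing.assert_allclose(p, _brute_force_probs(coef, sex, age, current),
                                       atol=1e-12)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert p.min() > 0


def test_simulation_is_seed_deterministic(params):
    a = h.simulate_panel(params.coefficients, n=500, waves=2, seed=9)
    b = h.simulate_panel(params.coefficients, n=500, waves=2, seed=9)
    assert a.equals(b)
    c = h.simulate_panel(params.coefficients, n=500, waves=2, seed=10)
    assert not a.equals(c)


def test_null_model_simulation_is_uniform_within_sampling_error():
    n = 50_000
    panel = h.simulate_panel(h.TransitionCoefficients.null(), n=n, waves=1, seed=2)
    nxt = ((panel.w1 * 2 + panel.p1) * 2 + panel.f1) * 2 + panel.v1
    counts = np.bincount(nxt, minlength=24)
    p = 1 / 24
    se = np.sqrt(p * (1 - p) / n)
    assert np.abs(counts / n - p).max() < 3 * se


def test_empirical_transitions_converge_to_model(params):
    coef = params.coefficients
    start = h.RiskProfile(1, 0, 1, 0)
    n = 40_000
    init = np.zeros(24)
    init[start.index] = 1.0
    panel = h.simulate_panel(coef, n=n, waves=1, seed=3, age_range=(40.0, 40.0),
                             male_fraction=0.0, initial=init)
    nxt = ((panel.w1 * 2 + panel.p1) * 2 + panel.f1) * 2 + panel.v1
    emp = np.bincount(nxt, minlength=24) / n
    model = h.transition_probabilities(coef, 0, 40.0, start)
    se = np.sqrt(model * (1 - model) / n)
    assert (np.abs(emp - model) < 4 * se + 1e-4).all()


def test_fit_recovers_parameters_small_model():
    rng = np.random.default_rng(7)
    terms = _small_structure()
    true = h.TransitionCoefficients(terms, rng.normal(0, 0.5, len(terms)))
    panel = h.simulate_panel(true, n=8_000, waves=1, seed=4)
    fit = h.fit_joint_logit(panel, structure=terms)
    z = np.abs(fit.values - true.values) / fit.se
    assert (z < 3.0).all()
    assert fit.grad_norm < 1e-6
    assert fit.loglik >= null_loglik(panel)


def test_fit_on_null_data_recovers_zero():
    panel = h.simulate_panel(h.TransitionCoefficients.null(), n=6_000, waves=1, seed=6)
    fit = h.fit_joint_logit(panel, structure=_small_structure())
    z = np.abs(fit.values) / fit.se
    assert (z < 3.0).all()


def test_per_cycle_matrix_two_year_rows_match_model(params):
    coef = params.coefficients
    M = h.per_cycle_matrix(coef, 1, 30.0, 2)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
    row = h.transition_probabilities(coef, 1, 30.0, h.RiskProfile(0, 1, 1, 0))
    np.testing.assert_allclose(M[h.RiskProfile(0, 1, 1, 0).index], row, atol=1e-12)


def test_annualized_matrix_squares_back(params):
    coef = params.coefficients
    M2 = h.per_cycle_matrix(coef, 0, 45.0, 2)
    M1 = h.per_cycle_matrix(coef, 0, 45.0, 1)
    np.testing.assert_allclose(M1.sum(axis=1), 1.0, atol=1e-12)
    assert (M1 >= 0).all()
    assert np.linalg.norm(M1 @ M1 - M2, "fro") < 1e-6


def test_near_identity_model_annualizes_to_near_identity():
    # huge own-status persistence makes the 2-year matrix nearly the identity,
    # which must survive the square root + projection: intercept -A with
    # own-status slope +2A penalizes both adding and dropping a component by A
    own = {"w1": "cw1", "w2": "cw2", "p1": "cp1", "f1": "cf1", "v1": "cv1"}
    terms = tuple(
        [Term((o,)) for o in own] + [Term((o,), c) for o, c in own.items()]
    )
    values = np.concatenate([np.full(5, -14.0), np.full(5, 28.0)])
    coef = h.TransitionCoefficients(terms, values)
    for cycle in (1, 2):
        M = h.per_cycle_matrix(coef, 0, 30.0, cycle)
        assert np.abs(M - np.eye(24)).max() < 1e-3


def test_default_structure_layout():
    terms = default_structure()
    assert len(terms) == 56
    assert len({t.name for t in terms}) == 56
    # round-trips through names
    assert all(Term.from_name(t.name) == t for t in terms)
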