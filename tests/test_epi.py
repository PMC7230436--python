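import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import healecon as h
from healecon.state_space import RiskProfile


class TestStandardization:
    def test_null_ratios(self):
        smr = h.standardize_ratios(h.CategoryRatios([1.0, 1.0], [0.5, 0.5]))
        np.testing.assert_allclose(smr, [1.0, 1.0])

    def test_binary_example(self):
        smr = h.standardize_ratios(h.CategoryRatios([1.0, 2.0], [0.5, 0.5]))
        np.testing.assert_allclose(smr, [2 / 3, 4 / 3])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_population_mean_is_one_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        cr = h.CategoryRatios(rng.uniform(0.2, 5.0, k), rng.dirichlet(np.ones(k)))
        smr = h.standardize_ratios(cr)
        assert cr.proportions @ smr == pytest.approx(1.0, abs=1e-12)
        again = h.standardize_ratios(h.CategoryRatios(smr, cr.proportions))
        np.testing.assert_allclose(again, smr, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            h.CategoryRatios([1.0, -1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            h.CategoryRatios([1.0, 1.0], [0.5, 0.4])


class TestCombinedHazard:
    def test_null_effects_reduce_to_baseline(self):
        dims = {k: h.CategoryRatios([1.0, 1.0], [0.5, 0.5]) for k in ("a", "b")}
        assert h.combined_hazard(0.01, dims, {"a": 1, "b": 0}) == pytest.approx(0.01)

    def test_two_binary_dimensions_product(self):
        cr = h.CategoryRatios([1.0, 2.0], [0.5, 0.5])
        dims = {"a": cr, "b": cr}
        h_star = h.combined_hazard(0.01, dims, {"a": 1, "b": 1})
        assert h_star == pytest.approx(0.01 * (4 / 3) ** 2)
        assert h_star == pytest.approx(0.017778, abs=5e-7)

    def test_population_expectation_recovers_baseline(self):
        # independent dimensions: E[product of mean-1 standardized terms] = 1
        rng = np.random.default_rng(0)
        dims = {
            name: h.CategoryRatios(rng.uniform(0.5, 3.0, 3), rng.dirichlet(np.ones(3)))
            for name in ("x", "y")
        }
        H = 0.02
        total = 0.0
        for i in range(3):
            for j in range(3):
                w = dims["x"].proportions[i] * dims["y"].proportions[j]
                total += w * h.combined_hazard(H, dims, {"x": i, "y": j})
        assert total == pytest.approx(H, abs=1e-12)

    def test_missing_dimension_raises(self):
        with pytest.raises(KeyError):
            h.combined_hazard(0.01, {}, {"weight": 0})


class TestAdjustedIncidence:
    def test_null_relative_risks(self):
        prof = RiskProfile(2, 1, 1, 1)
        ratios = {f: h.CategoryRatios(np.ones(3 if f == "weight" else 2),
                                      np.ones(3 if f == "weight" else 2) / (3 if f == "weight" else 2))
                  for f in ("weight", "activity", "fruit", "vegetable")}
        assert h.adjusted_incidence(0.02, ratios, prof) == pytest.approx(0.02)

    def test_single_factor_example_and_conservation(self):
        ratios = {"activity": h.CategoryRatios([1.0, 3.0], [0.5, 0.5])}
        unexposed = h.adjusted_incidence(0.02, ratios, RiskProfile(0, 0, 0, 0), ("activity",))
        exposed = h.adjusted_incidence(0.02, ratios, RiskProfile(0, 1, 0, 0), ("activity",))
        assert unexposed == pytest.approx(0.01)
        assert exposed == pytest.approx(0.03)
        assert 0.5 * unexposed + 0.5 * exposed == pytest.approx(0.02)

    def test_missing_linked_factor_raises(self):
        with pytest.raises(KeyError):
            h.adjusted_incidence(0.02, {}, RiskProfile(0, 0, 0, 0), ("fruit",))


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [(0.0, 1.0, 0.0), (0.01, 1.0, 0.009950), (0.03, 2.0, 0.058235)],
    )
    def test_closed_form(self, rate, t, expected):
        assert h.incidence_to_probability(rate, t) == pytest.approx(expected, abs=5e-7)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.0, 5.0), st.floats(0.1, 2.0))
    def test_bounds(self, rate, t):
        p = h.incidence_to_probability(rate, t)
        assert 0.0 <= p < 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            h.incidence_to_probability(-0.1, 1.0)


def _oracle_prevalence(incidence, p_a, mortality, ratio, interval):
    """Independent forward integration of the illness-death dynamics."""
    m_n = mortality / (1 - p_a + ratio * p_a)
    m_d = ratio * m_n

    def rhs(_, y):
        n, d = y
        return [-(incidence + m_n) * n, incidence * n - m_d * d]

    sol = solve_ivp(rhs, (0.0, interval), [1 - p_a, p_a], rtol=1e-12, atol=1e-14)
    n, d = sol.y[:, -1]
    return d / (n + d)


class TestSolveIncidence:
    def test_recovers_planted_incidence_on_grid(self):
        rng = np.random.default_rng(0)
        for p_a in (0.01, 0.05, 0.2):
            for mortality in (0.005, 0.02):
                for ratio in (1.0, 1.5, 3.0):
                    true = rng.uniform(0.001, 0.05)
                    p_b = _oracle_prevalence(true, p_a, mortality, ratio, 5.0)
                    est = h.solve_incidence(p_a, p_b, mortality, ratio, 5.0)
                    assert est == pytest.approx(true, abs=1e-6)

    def test_constant_prevalence_equal_mortality_needs_no_incidence(self):
        assert h.solve_incidence(0.1, 0.1, 0.01, 1.0, 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError, match="minimum achievable"):
            h.solve_incidence(0.2, 0.0001, 0.02, 3.0, 5.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            h.solve_incidence(1.5, 0.1, 0.01, 1.0, 5.0)
        with pytest.raises(ValueError):
            h.solve_incidence(0.1, 0.1, 0.01, 1.0, 0.0)


class TestPerCaseCost:
    def test_direct_arithmetic(self):
        assert h.per_case_cost(1000, 0.5, 0.25, 100) == pytest.approx(20.0)

    def test_zero_proportion_and_scaling(self):
        assert h.per_case_cost(1000, 0.0, 0.25, 100) == 0.0
        one = h.per_case_cost(1000, 0.5, 0.25, 100)
        assert h.per_case_cost(1000, 0.5, 0.25, 200) == pytest.approx(one / 2)

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            h.per_case_cost(1000, 0.5, 0.0, 100)
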