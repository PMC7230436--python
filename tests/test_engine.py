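import numpy as np
import pytest

import healecon as h
from healecon.state_space import DEAD_INDEX


class TestDiscounting:
    def test_year_zero_undiscounted(self):
        assert h.discount_factor(0.015, 0) == 1.0

    def test_one_year_at_default_rate(self):
        assert 50 * h.discount_factor(0.015, 1) == pytest.approx(49.2611, abs=5e-5)

    def test_two_year_program_cost(self):
        cost = 50 * h.discount_factor(0.015, 0) + 50 * h.discount_factor(0.015, 1)
        assert round(cost, 2) == 99.26


class TestCompetingIncidence:
    def test_single_disease_reduces_to_rate_transform(self):
        probs, stay = h.competing_incidence(np.array([0.03]))
        assert probs[0] == pytest.approx(h.incidence_to_probability(0.03, 1.0))
        assert probs.sum() + stay == pytest.approx(1.0, abs=1e-14)

    def test_equal_rates_split_equally(self):
        probs, stay = h.competing_incidence(np.array([0.02, 0.02]))
        assert probs[0] == pytest.approx(probs[1])
        assert probs.sum() + stay == pytest.approx(1.0, abs=1e-14)

    def test_small_rates_approach_independent_transforms(self):
        rates = np.array([1e-4, 2e-4, 5e-5])
        probs, _ = h.competing_incidence(rates)
        indep = -np.expm1(-rates)
        # allocation error is second order in the rates
        assert np.abs(probs - indep).max() < (rates.sum()) ** 2

    def test_zero_rates(self):
        probs, stay = h.competing_incidence(np.zeros(3))
        assert stay == 1.0 and probs.sum() == 0.0


class TestCohortRun:
    def test_identity_effect_equals_no_effect(self, params):
        a = h.run_cohort(params, None)
        b = h.run_cohort(params, h.ProgramEffect())
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_occupancy_conserved_and_dead_monotone(self, baseline_trace):
        sums = baseline_trace.occupancy.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-10
        dead = baseline_trace.occupancy[:, DEAD_INDEX]
        assert (np.diff(dead) >= -1e-15).all()
        assert dead[0] == 0.0

    def test_null_parameters_match_life_table_survival(self, null_params):
        trace = h.run_cohort(null_params)
        lt = null_params.life_table
        expected = {}
        for sex in ("female", "male"):
            H = np.array([lt.hazard(sex, float(a)) for a in null_params.cycle_ages()])
            expected[sex] = np.concatenate([[1.0], np.exp(-np.cumsum(H))])
        mix = null_params.sex_mix * expected["female"] + (1 - null_params.sex_mix) * expected["male"]
        np.testing.assert_allclose(trace.alive_fraction(), mix, atol=1e-12)

    def test_null_parameters_qalys_equal_discounted_life_expectancy(self, null_params):
        trace = h.run_cohort(null_params)
        dec = h.UtilityDecrements.from_params(null_params)
        q = h.qaly_total(trace, dec)
        alive = trace.alive_fraction()[:-1]
        df = (1 + null_params.discount_rate) ** (-np.arange(null_params.n_cycles, dtype=float))
        assert q == pytest.approx(float((alive * df).sum()), abs=1e-10)
        assert h.disease_years(trace) == 0.0

    def test_null_parameters_program_effect_is_inert(self, null_params, effect_full):
        dec = h.UtilityDecrements.from_params(null_params)
        base = h.qaly_total(h.run_cohort(null_params), dec)
        treated = h.qaly_total(h.run_cohort(null_params, effect_full), dec)
        assert treated == pytest.approx(base, abs=1e-10)

    def test_disease_states_never_revert(self, params):
        trace = h.run_cohort(params)
        in_disease = trace.occupancy[:, 24:DEAD_INDEX].sum(axis=1)
        dead = trace.occupancy[:, DEAD_INDEX]
        # people enter disease states and only leave through death
        entered = np.diff(in_disease + dead)
        assert (entered >= -1e-12).all()

    def test_age_beyond_life_table_raises(self, params):
        lt = params.life_table
        with pytest.raises(ValueError, match="support"):
            lt.hazard("female", 500.0)

    def test_monotone_benefits_on_effect_grid(self, params):
        dec = h.UtilityDecrements.from_params(params)
        tables = h.transition_tables(params)
        prev_q, prev_dy = -np.inf, np.inf
        for b in (1.0, 1.2, 1.5, 2.0):
            eff = h.ProgramEffect(obesity_or=0.7, activity_or=b, fruit_or=b, vegetable_or=b)
            trace = h.run_cohort(params, eff, tables)
            q, dy = h.qaly_total(trace, dec), h.disease_years(trace)
            assert q >= prev_q - 1e-12
            assert dy <= prev_dy + 1e-12
            prev_q, prev_dy = q, dy


class TestParameterValidation:
    def test_horizon_must_align_with_cycle(self, params):
        import dataclasses

        with pytest.raises(ValueError, match="multiple"):
            dataclasses.replace(params, horizon_years=83, cycle_years=2)

    def test_sex_mix_bounds(self, params):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(params, sex_mix=1.5)
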