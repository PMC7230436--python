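import numpy as np
import pytest

import healecon as h
from healecon.psa import beta_hyperparameters


SPEC = h.UncertaintySpec(
    incidence_cv=0.1,
    prevalence_cv=0.1,
    rr_log_sd=0.05,
    mortality_ratio_log_sd=0.05,
    coefficient_sd=0.02,
    initial_dist_ess=5_000,
)


class TestHyperparameters:
    def test_beta_moment_matching(self):
        a, b = beta_hyperparameters(0.2, 0.05)
        assert a / (a + b) == pytest.approx(0.2)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(0.05)

    def test_beta_from_ci(self):
        a, b = h.beta_from_ci(0.3, 0.2, 0.4)
        assert a / (a + b) == pytest.approx(0.3)

    def test_lognormal_from_ci(self):
        mu, sigma = h.lognormal_from_ci(2.0, 1.5, 2.7)
        assert np.exp(mu) == pytest.approx(2.0)
        assert sigma == pytest.approx(np.log(2.7 / 1.5) / 3.92)

    def test_invalid(self):
        with pytest.raises(ValueError):
            beta_hyperparameters(0.5, 0.9)
        with pytest.raises(ValueError):
            h.lognormal_from_ci(2.0, 3.0, 1.0)


class TestDraws:
    def test_zero_variance_returns_base_exactly(self, params):
        drawn = h.draw_parameter_set(params, h.UncertaintySpec(), rng_seed=0)
        assert drawn is params or np.array_equal(
            drawn.initial.as_array(), params.initial.as_array()
        )

    def test_draws_are_valid_and_seeded(self, params):
        a = h.draw_parameter_set(params, SPEC, rng_seed=4)
        b = h.draw_parameter_set(params, SPEC, rng_seed=4)
        assert np.array_equal(a.initial.as_array(), b.initial.as_array())
        assert np.array_equal(a.coefficients.values, b.coefficients.values)
        assert not np.array_equal(a.coefficients.values, params.coefficients.values)
        # drawn RRs keep the linkage pattern: unlinked entries stay at exactly 1
        for da, dbase in zip(a.diseases, params.diseases):
            for f, rr in dbase.relative_risks.items():
                fixed = rr == 1.0
                assert np.array_equal(da.relative_risks[f][fixed], rr[fixed])

    def test_beta_prevalence_mean_within_sampling_error(self, params):
        rng = np.random.default_rng(0)
        spec = h.UncertaintySpec(prevalence_cv=0.2)
        n = 2_000
        base = params.diseases[0].prevalence
        draws = np.array(
            [h.draw_parameter_set(params, spec, rng).diseases[0].prevalence for _ in range(n)]
        )
        se = base * 0.2 / np.sqrt(n)
        assert abs(draws.mean() - base) < 4 * se

    def test_lognormal_rr_median_near_point(self, params):
        rng = np.random.default_rng(1)
        spec = h.UncertaintySpec(rr_log_sd=0.2)
        disease = params.diseases[3]  # ischemic heart disease: all factors linked
        base = disease.relative_risks["weight"][2]
        draws = np.array(
            [
                h.draw_parameter_set(params, spec, rng).diseases[3].relative_risks["weight"][2]
                for _ in range(800)
            ]
        )
        assert np.median(draws) == pytest.approx(base, rel=0.05)


class TestRunPSA:
    def test_zero_variance_collapses_interval(self, params, effect_full):
        result = h.run_psa(params, h.UncertaintySpec(), effect_full, n_sims=4, seed=1)
        for s in result.summaries.values():
            assert s.lower == pytest.approx(s.point, rel=1e-12)
            assert s.upper == pytest.approx(s.point, rel=1e-12)

    def test_null_behaviour_ratio_interval_degenerate_at_one(self, params):
        result = h.run_psa(
            params, SPEC, h.ProgramEffect(obesity_or=0.7), n_sims=12, seed=2
        )
        s = result.summaries["icer_qaly_ratio"]
        assert s.lower == s.upper == s.point == 1.0

    def test_seed_determinism(self, params, effect_full):
        a = h.run_psa(params, SPEC, effect_full, n_sims=8, seed=3)
        b = h.run_psa(params, SPEC, effect_full, n_sims=8, seed=3)
        for k in a.summaries:
            assert a.summaries[k].lower == b.summaries[k].lower
            assert a.summaries[k].upper == b.summaries[k].upper

    def test_wider_parameter_uncertainty_widens_intervals(self, params, effect_full):
        import dataclasses

        wide = dataclasses.replace(
            SPEC,
            incidence_cv=0.3,
            rr_log_sd=0.2,
            mortality_ratio_log_sd=0.2,
            coefficient_sd=0.06,
        )
        widths = {"narrow": [], "wide": []}
        for seed in (0, 1, 2):
            for label, spec in (("narrow", SPEC), ("wide", wide)):
                res = h.run_psa(params, spec, effect_full, n_sims=15, seed=seed)
                s = res.summaries["icer_qaly_2"]
                widths[label].append(s.upper - s.lower)
        assert np.median(widths["wide"]) > np.median(widths["narrow"])

    def test_n_sims_validation(self, params, effect_full):
        with pytest.raises(ValueError):
            h.run_psa(params, SPEC, effect_full, n_sims=1, seed=0)
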