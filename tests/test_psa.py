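"""Distribution fitting, coupled epidemiological resampling, and PSA mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from pedometer_cea import pipeline as pl
from pedometer_cea.psa import (PSAResults, Table2Distributions, ceac, degenerate_draw,
                               fit_beta, run_psa, sample_epi, sample_normal_ci,
                               sample_squash_cost, squash_cost_from_x, summarize)

from conftest import make_epi


class TestFitBeta:
    @pytest.mark.parametrize("mean,lo,hi", [
        (0.375, 0.056, 0.789),
        (0.83, 0.54, 0.99),
        (0.50, 0.13, 0.87),
        (0.25, 0.08, 0.47),
    ])
    def test_recovers_stated_interval(self, mean, lo, hi):
        fit = fit_beta(mean, lo, hi)
        assert fit.alpha / (fit.alpha + fit.beta) == pytest.approx(mean, abs=1e-10)
        assert fit.q025 == pytest.approx(lo, abs=0.02)
        assert fit.q975 == pytest.approx(hi, abs=0.02)

    def test_symmetric_interval_gives_symmetric_fit(self):
        fit = fit_beta(0.5, 0.13, 0.87)
        assert fit.alpha == pytest.approx(fit.beta, rel=1e-9)
        narrow = fit_beta(0.5, 0.25, 0.75)
        assert narrow.alpha > fit.alpha

    def test_quantiles_against_numeric_integration(self):
        fit = fit_beta(0.375, 0.056, 0.789)
        for q, p in ((fit.q025, 0.025), (fit.q975, 0.975)):
            mass, _ = integrate.quad(lambda x: stats.beta.pdf(x, fit.alpha, fit.beta), 0, q)
            assert mass == pytest.approx(p, abs=1e-6)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_beta(0.5, 0.6, 0.9)


class TestSquashCost:
    def test_endpoints_and_mean(self):
        assert squash_cost_from_x(0.5) == pytest.approx(6.66)
        assert round(squash_cost_from_x(0.13), 2) == 3.37
        assert round(squash_cost_from_x(0.87), 2) == 9.95

    def test_monte_carlo_mean(self):
        rng = np.random.default_rng(21)
        draws = sample_squash_cost(rng, size=100_000)
        assert draws.mean() == pytest.approx(6.66, abs=0.05)


class TestNormalFromCI:
    def test_recovered_standard_deviation(self):
        rng = np.random.default_rng(5)
        draws = sample_normal_ci(2491, 1098, 3885, rng, size=100_000)
        assert draws.std() == pytest.approx((3885 - 1098) / 3.92, rel=0.02)
        assert draws.mean() == pytest.approx(2491, abs=10)

    def test_degenerate_interval_is_constant(self):
        rng = np.random.default_rng(0)
        assert sample_normal_ci(2491, 2491, 2491, rng) == 2491


class TestSampleEpi:
    def setup_method(self):
        self.epi = make_epi(ages=(50, 51), incidence=0.02, excess=0.01, prevalence=0.1)

    def test_large_exposure_converges_to_input(self):
        rng = np.random.default_rng(3)
        res = sample_epi(self.epi, rng, incidence_exposure=1e10, prevalence_n=10**9,
                         mortality_exposure=1e10)
        np.testing.assert_allclose(res.incidence, self.epi.incidence, rtol=1e-3)
        np.testing.assert_allclose(res.prevalence, self.epi.prevalence, rtol=1e-3)

    def test_deterministic_given_seed(self):
        a = sample_epi(self.epi, np.random.default_rng(9))
        b = sample_epi(self.epi, np.random.default_rng(9))
        np.testing.assert_array_equal(a.incidence, b.incidence)
        np.testing.assert_array_equal(a.prevalence, b.prevalence)

    def test_coupling_induces_rank_correlation_within_disease(self):
        n = 500

        def draws(couple):
            rng = np.random.default_rng(33)
            inc, mort = [], []
            for _ in range(n):
                s = sample_epi(self.epi, rng, incidence_exposure=1e4,
                               mortality_exposure=1e4, couple=couple)
                inc.append(s.incidence[0].mean())
                mort.append(s.excess_mortality[0].mean())
            return np.array(inc), np.array(mort)

        inc_c, mort_c = draws(couple=True)
        rho_coupled = stats.spearmanr(inc_c, mort_c).statistic
        inc_u, mort_u = draws(couple=False)
        rho_uncoupled = stats.spearmanr(inc_u, mort_u).statistic
        assert rho_coupled > 0.9
        assert abs(rho_uncoupled) < 0.15


class TestRunPSA:
    def test_degenerate_distributions_reproduce_base_case(self, inputs, base_report):
        res = run_psa(1, 123, pipeline_inputs=inputs, degenerate=True)
        row = res.runs.iloc[0]
        assert row["delta_qaly"] == base_report.ce.delta_qaly
        assert row["delta_ly"] == base_report.ce.delta_ly
        assert row["intervention_cost"] == base_report.ce.intervention_cost
        assert row["total_cost_incl"] == base_report.ce.total_cost_diff_included
        assert row["total_cost_excl"] == base_report.ce.total_cost_diff_excluded

    def test_degenerate_draw_sits_at_table_means(self):
        d = degenerate_draw(Table2Distributions())
        assert (d.f_gp, d.f_squash, d.f_accept) == (0.375, 0.83, 0.50)
        assert d.c_scoring == pytest.approx(6.66)
        assert (d.steps, d.maintenance) == (2491.0, 0.25)

    def test_reproducible_and_scatter_varies_with_seed(self, inputs):
        a = run_psa(5, 77, pipeline_inputs=inputs)
        b = run_psa(5, 77, pipeline_inputs=inputs)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        c = run_psa(5, 78, pipeline_inputs=inputs)
        assert not a.runs["delta_qaly"].equals(c.runs["delta_qaly"])


class TestCEAC:
    def test_limits_match_direct_counting(self, psa_results):
        r = psa_results.runs
        table = ceac(psa_results, [0.0, 1e12])
        assert table["probability"].iloc[0] == (r["total_cost_incl"] < 0).mean()
        assert table["probability"].iloc[-1] == (r["delta_qaly"] > 0).mean()

    def test_monotone_when_all_runs_in_tradeoff_quadrant(self, psa_results):
        r = psa_results.runs
        sub = PSAResults(runs=r[(r["delta_qaly"] > 0) & (r["total_cost_incl"] > 0)], seed=0)
        probs = ceac(sub, np.arange(0, 100_001, 5_000))["probability"].to_numpy()
        assert np.all(np.diff(probs) >= 0)
        assert np.all((0 <= probs) & (probs <= 1))

    def test_matches_direct_counting_on_grid(self, psa_results):
        lam = 15_000.0
        table = ceac(psa_results, [lam])
        r = psa_results.runs
        expected = ((lam * r["delta_qaly"] - r["total_cost_incl"]) > 0).mean()
        assert table["probability"].iloc[0] == expected


class TestSummarize:
    def test_ratio_of_means_vs_mean_of_ratios_toy(self):
        runs = pd.DataFrame({
            "delta_ly": [1.0, 1.0, 2.0], "delta_qaly": [1.0, 1.0, 2.0],
            "intervention_cost": [1.0, 2.0, 9.0],
            "future_cost_incl": [0.0, 0.0, 0.0], "future_cost_excl": [0.0, 0.0, 0.0],
            "total_cost_incl": [1.0, 2.0, 9.0], "total_cost_excl": [1.0, 2.0, 9.0],
        })
        s = summarize(PSAResults(runs=runs, seed=0))
        assert s["icer_per_qaly_incl"] == pytest.approx(3.0)       # (12/3) / (4/3)
        assert s["icer_per_qaly_mean_of_ratios"] == pytest.approx(2.5)

    def test_summary_intervals_cover_means(self, psa_results):
        s = summarize(psa_results)
        for key in ("life_years", "qalys", "intervention_cost"):
            assert s[key]["p2.5"] <= s[key]["mean"] <= s[key]["p97.5"]
        assert s["n_runs"] == psa_results.n_runs

    def test_cascade_cost_mean_matches_product_of_draw_means(self, inputs, psa_results):
        # pedometer-stage cost: base * f_gp * f_squash * f_target * f_accept * 19.95,
        # all draws independent, so the mean cost is the product of the means
        r = psa_results.runs
        base = inputs.config.cascade.base_population
        analytic = base * 0.375 * 0.83 * 0.441 * 0.50 * 19.95
        sampled = (base * r["f_gp"] * r["f_squash"] * 0.441 * r["f_accept"] * 19.95)
        assert sampled.mean() == pytest.approx(analytic, rel=3 * sampled.std() / np.sqrt(len(r)) / analytic)
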