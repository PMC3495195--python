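"""Cohort engine checks: closed forms, conservation, null effect, and an
individual-level microsimulation oracle run with the same rates."""

import numpy as np
import pandas as pd
import pytest

from pedometer_cea.disease_model import (CohortEngine, ScenarioSpec, diff_scenarios,
                                         init_cohorts, simulate, step_year)

from conftest import make_epi


def population_table(count, ages=(50,), split_sexes=True):
    rows = []
    for age in ages:
        if split_sexes:
            rows += [(age, "male", count // 2), (age, "female", count - count // 2)]
        else:
            rows += [(age, "male", count)]
    return pd.DataFrame(rows, columns=["age", "sex", "count"])


def uniform_pa(n_cohorts, dist=(1 / 3, 1 / 3, 1 / 3)):
    return np.broadcast_to(np.asarray(dist), (2, n_cohorts, 3)).copy()


class TestInitCohorts:
    def test_zero_prevalence_all_disease_free(self):
        epi = make_epi(prevalence=0.0)
        state = init_cohorts(population_table(1000), epi, uniform_pa(1))
        assert state.occupancy[..., 0].sum() == pytest.approx(1000)
        assert state.occupancy[..., 1:].sum() == 0

    def test_single_disease_split(self):
        epi = make_epi(diseases=("d",), prevalence=0.2)
        state = init_cohorts(population_table(1000), epi, uniform_pa(1))
        assert state.occupancy[..., 0].sum() == pytest.approx(800)
        assert state.occupancy[..., 1].sum() == pytest.approx(200)

    def test_two_disease_independence_products(self):
        epi = make_epi(prevalence=0.0)
        p1, p2 = 0.1, 0.3
        epi.prevalence[0, :, :] = p1
        epi.prevalence[1, :, :] = p2
        state = init_cohorts(population_table(1000), epi, uniform_pa(1))
        # states ordered by bitmask: {}, {d1}, {d2}, {d1,d2}
        expected = 1000 * np.array([(1 - p1) * (1 - p2), p1 * (1 - p2), (1 - p1) * p2, p1 * p2])
        np.testing.assert_allclose(state.occupancy.sum(axis=(0, 1, 2)), expected, rtol=1e-12)


class TestStepYear:
    def test_all_rates_zero_leaves_state_unchanged(self):
        epi = make_epi()
        state = init_cohorts(population_table(1000), epi, uniform_pa(1))
        nxt = step_year(state, epi)
        np.testing.assert_array_equal(nxt.occupancy, state.occupancy)
        assert nxt.year == state.year + 1
        assert nxt.dead.sum() == 0

    def test_constant_mortality_matches_exponential_survival(self):
        mu = 0.05
        epi = make_epi(ages=tuple(range(50, 60)), other_mortality=mu)
        state = init_cohorts(population_table(1000), epi, uniform_pa(1))
        for k in range(1, 6):
            state = step_year(state, epi)
            assert state.alive.sum() == pytest.approx(1000 * np.exp(-k * mu), abs=1e-9)
            assert state.total_mass.sum() == pytest.approx(1000, abs=1e-9)

    def test_half_cycle_person_years_closed_form(self):
        mu = 0.05
        epi = make_epi(ages=tuple(range(50, 60)), other_mortality=mu)
        engine = CohortEngine(epi, population_table(1000))
        out = engine.scenario_output(ScenarioSpec("x", uniform_pa(1)))
        expected = 1000 * 0.5 * (np.exp(-mu * (out.years - 1)) + np.exp(-mu * out.years))
        np.testing.assert_allclose(out.life_years, expected, atol=1e-9)


class TestMassConservation:
    def test_default_synthetic_parameters_full_horizon(self, inputs):
        final = inputs.engine.final_state
        np.testing.assert_allclose(final.total_mass, 1.0, atol=1e-9)
        assert np.all(final.occupancy >= -1e-15)


class TestNullEffect:
    def test_identical_outputs_for_any_pa_allocation(self):
        epi = make_epi(incidence=0.02, excess=0.03, prevalence=0.1,
                       other_mortality=0.01, utility=0.8)
        engine = CohortEngine(epi, population_table(1000))
        a = engine.scenario_output(ScenarioSpec("a", uniform_pa(1, (1, 0, 0))))
        b = engine.scenario_output(ScenarioSpec("b", uniform_pa(1, (0, 0.5, 0.5))))
        np.testing.assert_allclose(a.life_years, b.life_years, rtol=1e-12)
        np.testing.assert_allclose(a.qalys, b.qalys, rtol=1e-12)

    def test_flow_incrementals_exactly_zero(self):
        epi = make_epi(incidence=0.02, excess=0.03, prevalence=0.1,
                       other_mortality=0.01, utility=0.8, disease_cost=1000.0,
                       unrelated_cost=500.0)
        engine = CohortEngine(epi, population_table(1000))
        flows = np.zeros((2, 1, 3))
        flows[:, 0, :] = [50.0, 30.0, 20.0]
        inc = engine.incremental_from_flows(flows)
        assert np.all(inc.d_life_years == 0.0)
        assert np.all(inc.d_qalys == 0.0)
        assert np.all(inc.d_disease_costs == 0.0)
        assert np.all(inc.d_unrelated_costs == 0.0)


class TestMonotonicity:
    def test_higher_inactive_risk_cannot_reduce_gain_of_activation(self):
        gains = []
        for rr in (1.2, 1.5, 2.0, 3.0):
            epi = make_epi(ages=tuple(range(50, 70)), incidence=0.03, excess=0.08,
                           other_mortality=0.01, rr_inactive=rr, rr_insufficient=1.0)
            engine = CohortEngine(epi, population_table(1000))
            flows = np.zeros((2, 1, 3))
            flows[:, 0, 1] = 100.0  # inactive -> norm active
            gains.append(engine.incremental_from_flows(flows).d_life_years.sum())
        assert all(b >= a for a, b in zip(gains, gains[1:]))
        assert gains[0] > 0


def microsimulate(epi, n, years, pa_dist, seed):
    """Individual-level stochastic simulation with the same rates as the engine.

    Returns per-individual life-years and QALYs (half-year credit in the year
    of death), for comparison with the deterministic cohort model.
    """
    rng = np.random.default_rng(seed)
    D = epi.n_diseases
    sex = rng.integers(0, 2, n)
    age_idx = np.zeros(n, dtype=int)
    pa = rng.choice(3, n, p=pa_dist)
    present = np.zeros((n, D), dtype=bool)
    for d in range(D):
        present[:, d] = rng.uniform(size=n) < epi.prevalence[d, 0, sex]
    alive = np.ones(n, dtype=bool)
    ly = np.zeros(n)
    qaly = np.zeros(n)

    def weight(present_mat):
        w = np.ones(n)
        for d in range(D):
            w = np.where(present_mat[:, d], w * epi.utility[d], w)
        return w * epi.reference_utility[0, 0]

    for _ in range(years):
        start_alive = alive.copy()
        w_start = weight(present)
        mort = epi.other_mortality[age_idx, sex] + (present * epi.excess_mortality[:, 0, 0]).sum(1)
        dies = rng.uniform(size=n) < 1 - np.exp(-mort)
        new_present = present.copy()
        for d in range(D):
            rr_c = np.prod(np.where(present, epi.rr_comorbidity[d], 1.0), axis=1)
            rate = epi.incidence[d, age_idx, sex] * epi.rr_pa[d, pa] * rr_c
            acquires = (~present[:, d]) & (rng.uniform(size=n) < 1 - np.exp(-rate))
            new_present[:, d] |= acquires
        survived = start_alive & ~dies
        alive = survived
        w_end = weight(new_present)
        ly += np.where(start_alive, np.where(survived, 1.0, 0.5), 0.0)
        qaly += np.where(start_alive, 0.5 * (w_start + np.where(survived, w_end, 0.0)), 0.0)
        present = new_present
        age_idx += 1
    return ly, qaly


class TestMicrosimulationOracle:
    def test_cohort_model_within_monte_carlo_error(self):
        epi = make_epi(ages=(60, 61, 62, 63), incidence=0.10, excess=0.05,
                       prevalence=0.2, other_mortality=0.02, rr_inactive=1.5,
                       rr_insufficient=1.2, rr_comorbidity=2.0, utility=0.8,
                       reference_utility=0.9)
        n, years = 10_000, 3
        pa_dist = (0.3, 0.3, 0.4)
        engine = CohortEngine(epi, population_table(n, ages=(60,)), horizon=years)
        out = engine.scenario_output(ScenarioSpec("cohort", uniform_pa(1, pa_dist)))
        ly_i, qaly_i = microsimulate(epi, n, years, pa_dist, seed=17)
        for cohort_total, sample in ((out.life_years.sum(), ly_i), (out.qalys.sum(), qaly_i)):
            se = sample.std(ddof=1) * np.sqrt(n)
            assert abs(cohort_total - sample.sum()) < 3 * se


class TestScenarioOutputs:
    def test_horizon_zero_gives_empty_streams(self):
        epi = make_epi()
        out = simulate(ScenarioSpec("empty", uniform_pa(1), horizon=0), epi, population_table(10))
        assert len(out.years) == 0 and len(out.life_years) == 0

    def test_qalys_bounded_by_life_years(self, inputs):
        from pedometer_cea.pipeline import scenario_outputs, run_base_case

        report = run_base_case(inputs=inputs)
        ped, cur = scenario_outputs(inputs, report)
        for out in (ped, cur):
            assert np.all(out.qalys <= out.life_years + 1e-9)
            assert np.all(out.life_years >= 0)
            assert np.all(out.total_costs >= 0)

    def test_diff_identical_scenarios_is_zero(self):
        epi = make_epi(incidence=0.02, other_mortality=0.01)
        pop = population_table(500)
        out1 = simulate(ScenarioSpec("s", uniform_pa(1)), epi, pop)
        out2 = simulate(ScenarioSpec("s", uniform_pa(1)), epi, pop)
        d = diff_scenarios(out1, out2)
        assert np.all(d.d_life_years == 0) and np.all(d.d_qalys == 0)

    def test_excluded_costs_bounded_by_included_when_gaining_life(self, base_report):
        s = base_report.streams
        assert np.all(s.d_life_years >= -1e-9)
        # tolerance reflects subtractive cancellation on EUR 1e5-scale streams
        assert np.all(s.d_costs_excluded <= s.d_costs_included + 1e-6)
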