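"""End-to-end orchestration: from configuration to a deterministic CE report.

The deterministic base case chains the stages in the order the analysis runs:

1. intervention cascade -> completer count and intervention cost;
2. step effect -> sustained daily walking minutes;
3. survey records -> physical-activity class shift per age stratum;
4. shift x completers -> upward mover counts, allocated to age-sex cohorts;
5. cohort disease model -> incremental life-year, QALY and cost streams;
6. differential discounting -> ICERs per life year and per QALY.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeParams, CascadeResult, UnitCosts, run_cascade
from .config import PipelineConfig, config_hash
from .disease_model import CohortEngine, EpiParameters, IncrementalStreams, ScenarioSpec
from .economics import CEResult, DiscountRates, ce_result_from_streams
from .effect_translation import (EffectParams, PAClass, ShiftVector, TransitionCounts,
                                 derive_shift, transition_counts)
from .synthetic_data import (SurveyConfig, SyntheticEpiConfig, generate_epi_params,
                             generate_population, generate_survey)

__all__ = ["PipelineInputs", "BaseCaseReport", "build_inputs", "evaluate_pipeline", "run_base_case"]


@dataclass
class PipelineInputs:
    """Fixed inputs shared by the base case and all PSA runs."""

    config: PipelineConfig
    seed: int
    survey: pd.DataFrame
    population: pd.DataFrame
    epi: EpiParameters
    engine: CohortEngine

    @property
    def cascade_params(self) -> CascadeParams:
        c = self.config.cascade
        return CascadeParams(base_population=c.base_population, f_gp=c.f_gp, f_squash=c.f_squash,
                             f_target=c.f_target, f_accept=c.f_accept, f_followup=c.f_followup)

    @property
    def unit_costs(self) -> UnitCosts:
        c = self.config.costs
        return UnitCosts(c_approach=c.c_approach, c_scoring=c.c_scoring, c_counseling=c.c_counseling,
                         c_pedometer=c.c_pedometer, c_followup=c.c_followup)

    @property
    def effect_params(self) -> EffectParams:
        e = self.config.effect
        return EffectParams(steps_effect_1yr=e.steps_effect_1yr, step_pace=e.step_pace,
                            maintenance_fraction=e.maintenance_fraction)

    @property
    def discount_rates(self) -> DiscountRates:
        d = self.config.discount
        return DiscountRates(effects_rate=d.effects_rate, costs_rate=d.costs_rate)


def build_inputs(config: PipelineConfig | None = None, seed: int = 1) -> PipelineInputs:
    """Generate (or load) survey, population and epidemiology, and build the engine."""
    config = config or PipelineConfig()
    s = config.synth
    survey = generate_survey(
        s.n_survey, seed,
        SurveyConfig(walking_shape=s.walking_shape, walking_scale=s.walking_scale,
                     activity_slope=s.activity_slope, target_distribution=s.target_distribution,
                     tolerance=s.calibration_tolerance),
    )
    population = generate_population(int(config.cascade.base_population), (20, 65), seed + 1)
    if config.epi_csv_dir is not None:
        epi = EpiParameters.from_csv_dir(config.epi_csv_dir)
    else:
        epi = generate_epi_params(SyntheticEpiConfig(null_mode=s.null_epi))
    engine = CohortEngine(epi, population)
    return PipelineInputs(config=config, seed=seed, survey=survey, population=population,
                          epi=epi, engine=engine)


# ---------------------------------------------------------------------------
# shift -> cohort-level flows
# ---------------------------------------------------------------------------

def _stratum_masks(engine: CohortEngine, age_split: int) -> dict[str, np.ndarray]:
    ages = engine.start_ages
    return {f"<{age_split}": ages < age_split, f">={age_split}": ages >= age_split}


def baseline_pa_dist(engine: CohortEngine, shift: ShiftVector) -> np.ndarray:
    """Per-cohort baseline PA distribution: each stratum's survey distribution."""
    C = len(engine.start_ages)
    dist = np.zeros((2, C, 3))
    for name, mask in _stratum_masks(engine, shift.age_split).items():
        dist[:, mask, :] = shift.strata[name].baseline.proportions
    return dist


def completer_flows(engine: CohortEngine, shift: ShiftVector, completers: float,
                    ) -> tuple[np.ndarray, dict[str, TransitionCounts]]:
    """Allocate completers to strata and convert shifts to per-cohort mover masses.

    Completers are split across the two age strata in proportion to each
    stratum's population of not-norm-active persons (the target group), then
    each stratum's mover counts are spread over its age-sex cells in
    proportion to cell population. Returns ``flows[sex, cohort, k]`` for the
    three upward transitions and the per-stratum transition counts.
    """
    masks = _stratum_masks(engine, shift.age_split)
    weights = {}
    for name, mask in masks.items():
        st = shift.strata[name]
        not_norm = 1.0 - st.baseline[PAClass.NORM_ACTIVE]
        weights[name] = engine.mass[:, mask].sum() * not_norm
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("no target population in any stratum")
    C = len(engine.start_ages)
    flows = np.zeros((2, C, 3))
    transitions: dict[str, TransitionCounts] = {}
    for name, mask in masks.items():
        st = shift.strata[name]
        completers_st = completers * weights[name] / total_w
        trans = transition_counts(st.shift, st.baseline, completers_st)
        transitions[name] = trans
        stratum_pop = engine.mass[:, mask].sum()
        if stratum_pop > 0:
            cell_share = engine.mass[:, mask] / stratum_pop  # (2, n_cells)
            per_kind = np.array([trans.inactive_to_insufficient,
                                 trans.inactive_to_norm,
                                 trans.insufficient_to_norm])
            flows[:, mask, :] = cell_share[:, :, None] * per_kind[None, None, :]
    return flows, transitions


def pedometer_pa_dist(engine: CohortEngine, baseline: np.ndarray, flows: np.ndarray) -> np.ndarray:
    """Post-intervention PA allocation: baseline plus the mover flows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(engine.mass[:, :, None] > 0, flows / engine.mass[:, :, None], 0.0)
    delta = np.stack([-(frac[..., 0] + frac[..., 1]),
                      frac[..., 0] - frac[..., 2],
                      frac[..., 1] + frac[..., 2]], axis=-1)
    dist = baseline + delta
    if np.any(dist < -1e-9):
        raise ValueError("intervention shift exceeds available class mass in a cohort")
    return np.clip(dist, 0.0, None)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_pipeline(inputs: PipelineInputs, cascade_params: CascadeParams | None = None,
                      unit_costs: UnitCosts | None = None, effect_params: EffectParams | None = None,
                      *, epi: EpiParameters | None = None,
                      engine: CohortEngine | None = None) -> CEResult:
    """Run the full deterministic chain for one parameter set and return the CE result."""
    cascade_params = cascade_params or inputs.cascade_params
    unit_costs = unit_costs or inputs.unit_costs
    effect_params = effect_params or inputs.effect_params
    cascade = run_cascade(cascade_params, unit_costs)
    delta_minutes = effect_params.long_term_minutes()
    shift = derive_shift(inputs.survey, delta_minutes, inputs.config.age_split)
    if engine is None:
        engine = inputs.engine if (epi is None or epi is inputs.epi) else CohortEngine(epi, inputs.population)
    flows, _ = completer_flows(engine, shift, cascade.completers_exact)
    streams = engine.incremental_from_flows(flows)
    return ce_result_from_streams(streams, cascade.total_cost, inputs.discount_rates)


@dataclass
class BaseCaseReport:
    """Full deterministic report: cascade table, streams, and CE summary."""

    config_hash: str
    seed: int
    cascade: CascadeResult
    delta_minutes: float
    shift: ShiftVector
    transitions: dict[str, TransitionCounts]
    streams: IncrementalStreams
    ce: CEResult

    def streams_frame(self) -> pd.DataFrame:
        s = self.streams
        return pd.DataFrame({
            "year": s.years,
            "delta_life_years": s.d_life_years,
            "delta_qalys": s.d_qalys,
            "delta_disease_costs": s.d_disease_costs,
            "delta_unrelated_costs": s.d_unrelated_costs,
            "cum_delta_life_years": np.cumsum(s.d_life_years),
            "cum_delta_qalys": np.cumsum(s.d_qalys),
        })

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cascade.to_frame().to_csv(outdir / "cascade.csv", index=False)
        self.streams_frame().to_csv(outdir / "incremental_streams.csv", index=False)
        self.ce.to_json(outdir / "ce_result.json", config_hash=self.config_hash, seed=self.seed,
                        delta_minutes=self.delta_minutes,
                        transitions={k: v.display for k, v in self.transitions.items()})


def run_base_case(config: PipelineConfig | None = None, seed: int = 1,
                  outdir: str | Path | None = None,
                  inputs: PipelineInputs | None = None) -> BaseCaseReport:
    """Deterministic base-case evaluation; optionally writes the report files."""
    inputs = inputs or build_inputs(config, seed=seed)
    config = inputs.config
    cascade = run_cascade(inputs.cascade_params, inputs.unit_costs)
    delta_minutes = inputs.effect_params.long_term_minutes()
    shift = derive_shift(inputs.survey, delta_minutes, config.age_split)
    flows, transitions = completer_flows(inputs.engine, shift, cascade.completers_exact)
    streams = inputs.engine.incremental_from_flows(flows)
    ce = ce_result_from_streams(streams, cascade.total_cost, inputs.discount_rates)
    report = BaseCaseReport(
        config_hash=config_hash(config), seed=inputs.seed, cascade=cascade,
        delta_minutes=delta_minutes, shift=shift, transitions=transitions,
        streams=streams, ce=ce,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def scenario_outputs(inputs: PipelineInputs, report: BaseCaseReport):
    """Current-practice and pedometer scenario outputs (Figure-1-style absolute streams)."""
    baseline = baseline_pa_dist(inputs.engine, report.shift)
    flows, _ = completer_flows(inputs.engine, report.shift, report.cascade.completers_exact)
    pedometer = pedometer_pa_dist(inputs.engine, baseline, flows)
    cur = inputs.engine.scenario_output(ScenarioSpec("current_practice", baseline))
    ped = inputs.engine.scenario_output(ScenarioSpec("pedometer", pedometer))
    return ped, cur
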