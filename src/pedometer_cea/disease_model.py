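"""Discrete-time multi-state cohort model of chronic disease and mortality.

The engine follows the structure of chronic-disease models in the tradition of
the RIVM Chronic Disease Model: a closed cohort, stratified by sex, one-year
age class and physical-activity class, moves annually through health states
defined by the *set* of diseases present (all 2^D combinations of the D
modelled diseases, plus death). Disease incidence depends on the
physical-activity class through relative risks and on the other diseases
already present through comorbidity relative risks; mortality is the sum of a
background (other-cause) rate and the excess rates of the diseases present.

Rates are converted to annual transition probabilities as 1 - exp(-rate).
Within a cycle, mortality is applied first, then disease acquisitions
(independent across diseases given the current state), then age increments.
Person-years use the half-cycle correction (average of start- and end-of-cycle
occupancy). Cohorts exit the model after living through the cycle at the
oldest modelled age.

Because the dynamics are linear in cohort mass, the engine simulates each
(sex, PA class, starting age) cohort once at unit mass and obtains any
scenario — and any *incremental* contrast between scenarios that differ only
in their PA-class allocation — by weighting those unit streams. Incremental
streams are assembled in "flow form", as sums of class-to-class mover masses
times differences of unit streams, so that a null intervention (all PA
relative risks equal to one) yields incremental streams that are exactly
zero in floating-point arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effect_translation import PAClass

__all__ = [
    "SEXES",
    "EpiParameters",
    "CohortState",
    "ScenarioSpec",
    "ScenarioOutput",
    "IncrementalStreams",
    "CohortEngine",
    "init_cohorts",
    "step_year",
    "simulate",
    "diff_scenarios",
]

SEXES = ("male", "female")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class EpiParameters:
    """Age- and sex-specific epidemiological parameters driving the model.

    Array axis conventions: diseases ``(D,)``, ages ``(A,)``, sexes ``(2,)``
    in the order of :data:`SEXES`, PA classes ``(3,)`` in the order of
    :class:`~pedometer_cea.effect_translation.PAClass`.

    Attributes
    ----------
    incidence, excess_mortality, prevalence, disease_cost : (D, A, 2)
        Annual incidence and excess-mortality rates (per person-year),
        baseline prevalence proportions, and annual per-patient disease cost
        (EUR).
    rr_pa : (D, 3)
        Relative risk of incidence per PA class (norm active = 1).
    rr_comorbidity : (D, D)
        ``rr_comorbidity[d, e]`` multiplies the incidence of disease ``d``
        when disease ``e`` is present.
    utility : (D,)
        Disease-specific utility weight in [0, 1].
    unrelated_cost, other_mortality, reference_utility : (A, 2)
        Annual per-capita cost of care unrelated to the modelled diseases,
        other-cause mortality rate, and the utility of a disease-free person.
    utility_combination : str
        ``"multiplicative"`` (product of disease utilities) or ``"additive"``
        (1 minus summed decrements, floored at 0) for comorbid states.
    """

    diseases: tuple[str, ...]
    ages: np.ndarray
    incidence: np.ndarray
    excess_mortality: np.ndarray
    prevalence: np.ndarray
    rr_pa: np.ndarray
    rr_comorbidity: np.ndarray
    utility: np.ndarray
    disease_cost: np.ndarray
    unrelated_cost: np.ndarray
    other_mortality: np.ndarray
    reference_utility: np.ndarray
    utility_combination: str = "multiplicative"

    def __post_init__(self) -> None:
        self.diseases = tuple(self.diseases)
        self.ages = np.asarray(self.ages, dtype=int)
        D, A = len(self.diseases), len(self.ages)
        shapes = {
            "incidence": (D, A, 2),
            "excess_mortality": (D, A, 2),
            "prevalence": (D, A, 2),
            "disease_cost": (D, A, 2),
            "rr_pa": (D, 3),
            "rr_comorbidity": (D, D),
            "utility": (D,),
            "unrelated_cost": (A, 2),
            "other_mortality": (A, 2),
            "reference_utility": (A, 2),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        for name in ("incidence", "excess_mortality", "prevalence", "disease_cost",
                     "unrelated_cost", "other_mortality"):
            if np.any(getattr(self, name) < 0) or not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite and >= 0")
        if np.any(self.prevalence > 1):
            raise ValueError("prevalence must lie in [0, 1]")
        if np.any(self.rr_pa <= 0) or np.any(self.rr_comorbidity <= 0):
            raise ValueError("relative risks must be > 0")
        for name in ("utility", "reference_utility"):
            u = getattr(self, name)
            if np.any(u < 0) or np.any(u > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.utility_combination not in ("multiplicative", "additive"):
            raise ValueError("utility_combination must be 'multiplicative' or 'additive'")
        if "breast_cancer" in self.diseases:
            d = self.diseases.index("breast_cancer")
            male = slice(None), 0
            for name in ("incidence", "excess_mortality", "prevalence"):
                if np.any(getattr(self, name)[d][male] != 0):
                    raise ValueError(f"breast cancer {name} must be zero for males")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_states(self) -> int:
        return 1 << self.n_diseases

    def age_index(self, ages) -> np.ndarray:
        idx = np.searchsorted(self.ages, np.asarray(ages))
        if np.any(idx >= len(self.ages)) or np.any(self.ages[np.minimum(idx, len(self.ages) - 1)] != np.asarray(ages)):
            raise ValueError("ages outside the parameter age range")
        return idx

    # -- CSV round trip -----------------------------------------------------

    def to_csv_dir(self, directory: str | Path) -> None:
        """Write the parameter set as plain CSV tables into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for di, d in enumerate(self.diseases):
            for ai, a in enumerate(self.ages):
                for si, s in enumerate(SEXES):
                    rows.append((d, a, s, self.incidence[di, ai, si], self.excess_mortality[di, ai, si],
                                 self.prevalence[di, ai, si], self.disease_cost[di, ai, si]))
        pd.DataFrame(rows, columns=["disease", "age", "sex", "incidence", "excess_mortality",
                                    "prevalence", "disease_cost"]).to_csv(directory / "rates.csv", index=False)
        pd.DataFrame(
            [(d, c.name.lower(), self.rr_pa[di, int(c)]) for di, d in enumerate(self.diseases) for c in PAClass],
            columns=["disease", "pa_class", "rr"],
        ).to_csv(directory / "pa_relative_risks.csv", index=False)
        pd.DataFrame(
            [(d, e, self.rr_comorbidity[di, ei]) for di, d in enumerate(self.diseases)
             for ei, e in enumerate(self.diseases)],
            columns=["disease", "comorbid_with", "rr"],
        ).to_csv(directory / "comorbidity.csv", index=False)
        pd.DataFrame({"disease": list(self.diseases), "utility": self.utility}).to_csv(
            directory / "utilities.csv", index=False)
        rows = []
        for ai, a in enumerate(self.ages):
            for si, s in enumerate(SEXES):
                rows.append((a, s, self.other_mortality[ai, si], self.unrelated_cost[ai, si],
                             self.reference_utility[ai, si]))
        pd.DataFrame(rows, columns=["age", "sex", "other_mortality", "unrelated_cost",
                                    "reference_utility"]).to_csv(directory / "background.csv", index=False)

    @classmethod
    def from_csv_dir(cls, directory: str | Path, utility_combination: str = "multiplicative") -> "EpiParameters":
        directory = Path(directory)
        rates = pd.read_csv(directory / "rates.csv")
        diseases = tuple(dict.fromkeys(rates["disease"]))
        ages = np.array(sorted(rates["age"].unique()))
        D, A = len(diseases), len(ages)
        didx = {d: i for i, d in enumerate(diseases)}
        aidx = {a: i for i, a in enumerate(ages)}
        sidx = {s: i for i, s in enumerate(SEXES)}
        arrays = {k: np.zeros((D, A, 2)) for k in ("incidence", "excess_mortality", "prevalence", "disease_cost")}
        for row in rates.itertuples():
            key = didx[row.disease], aidx[row.age], sidx[row.sex]
            for k in arrays:
                arrays[k][key] = getattr(row, k)
        rr_pa = np.ones((D, 3))
        for row in pd.read_csv(directory / "pa_relative_risks.csv").itertuples():
            rr_pa[didx[row.disease], int(PAClass[row.pa_class.upper()])] = row.rr
        rr_c = np.ones((D, D))
        for row in pd.read_csv(directory / "comorbidity.csv").itertuples():
            rr_c[didx[row.disease], didx[row.comorbid_with]] = row.rr
        util = pd.read_csv(directory / "utilities.csv").set_index("disease")["utility"]
        background = pd.read_csv(directory / "background.csv")
        bg = {k: np.zeros((A, 2)) for k in ("other_mortality", "unrelated_cost", "reference_utility")}
        for row in background.itertuples():
            for k in bg:
                bg[k][aidx[row.age], sidx[row.sex]] = getattr(row, k)
        return cls(
            diseases=diseases, ages=ages, rr_pa=rr_pa, rr_comorbidity=rr_c,
            utility=np.array([util[d] for d in diseases]), utility_combination=utility_combination,
            **arrays, **bg,
        )


# ---------------------------------------------------------------------------
# state and transition machinery
# ---------------------------------------------------------------------------

@dataclass
class CohortState:
    """Occupancy of all cohorts at one point in model time.

    ``occupancy[sex, pa, cohort, state]`` holds person-mass in each disease-set
    compartment; ``dead[sex, pa, cohort]`` the absorbed mass. Cohort ``c`` has
    current age ``start_ages[c] + year``.
    """

    start_ages: np.ndarray
    occupancy: np.ndarray  # (2, 3, C, 2**D)
    dead: np.ndarray       # (2, 3, C)
    year: int = 0

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy.sum(axis=-1)

    @property
    def total_mass(self) -> np.ndarray:
        return self.alive + self.dead

    def current_ages(self) -> np.ndarray:
        return self.start_ages + self.year


def _state_masks(n_diseases: int) -> np.ndarray:
    """Boolean membership masks: present[d, S] == disease d in state S."""
    states = np.arange(1 << n_diseases)
    return (states[None, :] >> np.arange(n_diseases)[:, None]) & 1 == 1


def _comorbidity_multipliers(params: EpiParameters) -> np.ndarray:
    """(D, S) incidence multiplier on disease d from the diseases in state S."""
    present = _state_masks(params.n_diseases)
    logs = np.log(params.rr_comorbidity)  # (D, D)
    return np.exp(np.einsum("de,eS->dS", logs, present.astype(float)))


def build_transition_matrices(params: EpiParameters) -> tuple[np.ndarray, np.ndarray]:
    """One-year transition machinery for every (sex, PA class, age) slice.

    Returns ``(M, q)``: ``M[s, p, a, i, j]`` is the probability of moving from
    disease-set ``i`` to ``j`` while surviving the year, and ``q[s, p, a, i]``
    the probability of dying during the year. Rows of ``M`` sum to ``1 - q``.
    """
    D, A, S = params.n_diseases, len(params.ages), params.n_states
    present = _state_masks(D)                      # (D, S)
    pres_f = present.astype(float)
    # mortality: other-cause + excess of present diseases; (2, A, S), same for every pa class
    excess = np.einsum("dac,dS->caS", params.excess_mortality, pres_f)
    mort_rate = params.other_mortality.T[:, :, None] + excess
    q = 1.0 - np.exp(-mort_rate)                   # (2, A, S)
    # incidence probability of disease d given state S, pa class p: (2, 3, A, S, D)
    cm = _comorbidity_multipliers(params)          # (D, S)
    eff = (
        params.incidence[None, :, :, :]            # (1, D, A, 2)
        * params.rr_pa.T[:, :, None, None]         # (3, D, 1, 1)
    )                                              # (3, D, A, 2)
    eff = np.einsum("pdac,dS->cpaSd", eff, cm)     # (2, 3, A, S, D)
    p_acq = 1.0 - np.exp(-eff)
    # factorized acquisition transition: product over diseases of 2x2 factors
    T = np.ones((2, 3, A, S, S))
    src = present[:, :, None]                      # (D, S_src, 1)
    dst = present[:, None, :]                      # (D, 1, S_dst)
    for d in range(D):
        keep = src[d] & dst[d]                     # present stays present
        lose = src[d] & ~dst[d]                    # impossible
        gain = (~src[d]) & dst[d]
        stay = (~src[d]) & ~dst[d]
        pd_ = p_acq[..., d]                        # (2, 3, A, S)
        F = (
            keep.astype(float)[None, None, None]
            + gain[None, None, None] * pd_[..., None]
            + stay[None, None, None] * (1.0 - pd_[..., None])
        )
        F = np.where(lose[None, None, None], 0.0, F)
        T *= F
    if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
        raise ValueError("transition probabilities outside [0, 1]: corrupted rates")
    M = (1.0 - q)[:, None, :, :, None] * T
    return M, np.broadcast_to(q[:, None], (2, 3, A, S)).copy()


def _population_to_arrays(population: pd.DataFrame, params: EpiParameters) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a (age, sex, count) table to start ages (C,) and masses (2, C)."""
    ages = np.array(sorted(population["age"].unique()))
    mass = np.zeros((2, len(ages)))
    aidx = {a: i for i, a in enumerate(ages)}
    sidx = {s: i for i, s in enumerate(SEXES)}
    for row in population.itertuples():
        mass[sidx[row.sex], aidx[row.age]] += row.count
    params.age_index(ages)  # validates coverage
    return ages, mass


def _initial_state_dist(params: EpiParameters, age_idx: np.ndarray) -> np.ndarray:
    """Disease-set distribution from baseline prevalences, independence assumed.

    Returns (2, C, S): product over diseases of prev / (1 - prev) factors.
    """
    D = params.n_diseases
    present = _state_masks(D)
    prev = params.prevalence[:, age_idx, :]        # (D, C, 2)
    dist = np.ones((2, len(age_idx), params.n_states))
    for d in range(D):
        pd_ = prev[d].T[:, :, None]                # (2, C, 1)
        dist *= np.where(present[d][None, None, :], pd_, 1.0 - pd_)
    return dist


def init_cohorts(population: pd.DataFrame, params: EpiParameters, pa_dist: np.ndarray) -> CohortState:
    """Initialize cohorts from a population table and PA-class allocation.

    ``pa_dist[sex, cohort, class]`` gives each (sex, age) cell's distribution
    over the three PA classes; disease-set compartments are filled from the
    baseline prevalences assuming independence across diseases.
    """
    ages, mass = _population_to_arrays(population, params)
    pa_dist = np.asarray(pa_dist, dtype=float)
    if pa_dist.shape != (2, len(ages), 3):
        raise ValueError(f"pa_dist must have shape (2, {len(ages)}, 3)")
    if np.any(pa_dist < -1e-12) or np.any(np.abs(pa_dist.sum(axis=-1) - 1) > 1e-9):
        raise ValueError("pa_dist rows must be distributions over the three classes")
    dist = _initial_state_dist(params, params.age_index(ages))  # (2, C, S)
    occ = mass[:, None, :, None] * pa_dist.transpose(0, 2, 1)[:, :, :, None] * dist[:, None, :, :]
    return CohortState(
        start_ages=ages,
        occupancy=occ,
        dead=np.zeros((2, 3, len(ages))),
        year=0,
    )


def step_year(state: CohortState, params: EpiParameters,
              matrices: tuple[np.ndarray, np.ndarray] | None = None) -> CohortState:
    """Advance every cohort by one annual cycle (mortality, then incidence, then aging)."""
    M, _q = matrices if matrices is not None else build_transition_matrices(params)
    max_idx = len(params.ages) - 1
    cur = params.age_index(state.start_ages) + state.year
    active = cur <= max_idx
    idx = np.minimum(cur, max_idx)
    Mt = M[:, :, idx]                              # (2, 3, C, S, S)
    new = np.einsum("spcij,spci->spcj", Mt, state.occupancy)
    new[:, :, ~active] = 0.0
    dead = state.dead + state.occupancy.sum(-1) - new.sum(-1)
    # cohorts that just lived through the oldest modelled age exit the model
    exiting = cur == max_idx
    if np.any(exiting):
        dead[:, :, exiting] += new[:, :, exiting].sum(-1)
        new[:, :, exiting] = 0.0
    return CohortState(start_ages=state.start_ages, occupancy=new, dead=dead, year=state.year + 1)


# ---------------------------------------------------------------------------
# scenario simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario is a PA-class allocation plus an optional horizon.

    ``pa_dist[sex, cohort, class]`` — e.g. the current-practice baseline, or
    the post-intervention allocation after applying mover counts. With
    ``horizon=None`` the model runs until every cohort passes the oldest
    modelled age.
    """

    label: str
    pa_dist: np.ndarray
    horizon: int | None = None


@dataclass
class ScenarioOutput:
    """Per-cycle streams for one scenario (year 1 = first cycle after t=0)."""

    label: str
    years: np.ndarray
    life_years: np.ndarray
    qalys: np.ndarray
    disease_costs: np.ndarray
    unrelated_costs: np.ndarray

    @property
    def total_costs(self) -> np.ndarray:
        return self.disease_costs + self.unrelated_costs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "life_years": self.life_years,
                "qalys": self.qalys,
                "disease_costs": self.disease_costs,
                "unrelated_costs": self.unrelated_costs,
            }
        )


@dataclass
class IncrementalStreams:
    """Per-cycle incremental streams (pedometer minus current practice)."""

    years: np.ndarray
    d_life_years: np.ndarray
    d_qalys: np.ndarray
    d_disease_costs: np.ndarray
    d_unrelated_costs: np.ndarray

    @property
    def d_costs_included(self) -> np.ndarray:
        """Cost difference including unrelated care in life years gained."""
        return self.d_disease_costs + self.d_unrelated_costs

    @property
    def d_costs_excluded(self) -> np.ndarray:
        """Cost difference excluding unrelated care in incremental person-years."""
        return self.d_disease_costs


class CohortEngine:
    """Precomputed unit-mass cohort streams for fast scenario weighting.

    Simulates every (sex, PA class, starting age) cohort once at unit mass and
    stores its per-year life-year, QALY and cost streams. Scenario outputs and
    incremental contrasts are then inner products with cohort masses.
    """

    def __init__(self, params: EpiParameters, population: pd.DataFrame, horizon: int | None = None):
        self.params = params
        self.start_ages, self.mass = _population_to_arrays(population, params)
        self.matrices = build_transition_matrices(params)
        max_cycles = len(params.ages) - int(params.age_index(self.start_ages).min())
        self.horizon = max_cycles if horizon is None else min(horizon, max_cycles)
        self._run_unit_cohorts()

    def _run_unit_cohorts(self) -> None:
        p = self.params
        C = len(self.start_ages)
        age_idx = p.age_index(self.start_ages)
        dist = _initial_state_dist(p, age_idx)     # (2, C, S)
        occ = np.broadcast_to(dist[:, None], (2, 3, C, p.n_states)).copy()
        state = CohortState(start_ages=self.start_ages, occupancy=occ, dead=np.zeros((2, 3, C)))
        present = _state_masks(p.n_diseases)
        if p.utility_combination == "multiplicative":
            util_state = np.prod(np.where(present, p.utility[:, None], 1.0), axis=0)
        else:
            util_state = np.clip(1.0 - (present * (1.0 - p.utility[:, None])).sum(0), 0.0, None)
        T = self.horizon
        self.ly_u = np.zeros((T, 2, 3, C))
        self.qaly_u = np.zeros((T, 2, 3, C))
        self.dcost_u = np.zeros((T, 2, 3, C))
        self.ucost_u = np.zeros((T, 2, 3, C))
        max_idx = len(p.ages) - 1
        for t in range(T):
            cur = np.minimum(age_idx + t, max_idx)
            nxt = step_year(state, p, self.matrices)
            mid = 0.5 * (state.occupancy + nxt.occupancy)
            # exit at max age removed end-of-cycle mass from nxt; reconstruct the
            # pre-exit end mass for person-year counting
            if np.any(age_idx + t == max_idx):
                M, _ = self.matrices
                ex = age_idx + t == max_idx
                end_ex = np.einsum("spcij,spci->spcj", M[:, :, cur[ex]], state.occupancy[:, :, ex])
                mid[:, :, ex] = 0.5 * (state.occupancy[:, :, ex] + end_ex)
            alive_mid = mid.sum(-1)
            self.ly_u[t] = alive_mid
            ref = p.reference_utility[cur].transpose(1, 0)       # (2, C) ages x sex -> sex, C
            self.qaly_u[t] = np.einsum("spcS,S->spc", mid, util_state) * ref[:, None, :]
            prev_mass = np.einsum("spcS,dS->dspc", mid, present.astype(float))
            dc = p.disease_cost[:, cur, :].transpose(0, 2, 1)    # (D, 2, C)
            self.dcost_u[t] = np.einsum("dspc,dsc->spc", prev_mass, dc)
            uc = p.unrelated_cost[cur].transpose(1, 0)           # (2, C)
            self.ucost_u[t] = alive_mid * uc[:, None, :]
            state = nxt
        self.final_state = state

    def scenario_output(self, spec: ScenarioSpec) -> ScenarioOutput:
        pa = np.asarray(spec.pa_dist, dtype=float)
        C = len(self.start_ages)
        if pa.shape != (2, C, 3):
            raise ValueError(f"pa_dist must have shape (2, {C}, 3)")
        mass = self.mass[:, None, :] * pa.transpose(0, 2, 1)     # (2, 3, C)
        T = self.horizon if spec.horizon is None else min(spec.horizon, self.horizon)
        years = np.arange(1, T + 1)
        weigh = lambda u: np.einsum("tspc,spc->t", u[:T], mass)
        return ScenarioOutput(
            label=spec.label,
            years=years,
            life_years=weigh(self.ly_u),
            qalys=weigh(self.qaly_u),
            disease_costs=weigh(self.dcost_u),
            unrelated_costs=weigh(self.ucost_u),
        )

    def incremental_from_flows(self, flows: np.ndarray) -> IncrementalStreams:
        """Incremental streams from per-cohort upward mover masses.

        ``flows[sex, cohort, k]`` holds person-masses for the three upward
        transitions k: inactive->insufficient, inactive->norm,
        insufficient->norm. Computed as sums of ``flow * (unit stream of the
        destination class - unit stream of the source class)``, which is
        exactly zero when the PA class does not affect the dynamics.
        """
        f = np.asarray(flows, dtype=float)
        C = len(self.start_ages)
        if f.shape != (2, C, 3):
            raise ValueError(f"flows must have shape (2, {C}, 3)")
        pairs = ((0, 1), (0, 2), (1, 2))  # (source class, destination class)

        def contrast(u: np.ndarray) -> np.ndarray:
            out = np.zeros(self.horizon)
            for k, (src, dst) in enumerate(pairs):
                out += np.einsum("tsc,sc->t", u[:, :, dst, :] - u[:, :, src, :], f[:, :, k])
            return out

        return IncrementalStreams(
            years=np.arange(1, self.horizon + 1),
            d_life_years=contrast(self.ly_u),
            d_qalys=contrast(self.qaly_u),
            d_disease_costs=contrast(self.dcost_u),
            d_unrelated_costs=contrast(self.ucost_u),
        )


def simulate(spec: ScenarioSpec, params: EpiParameters, population: pd.DataFrame) -> ScenarioOutput:
    """Simulate one scenario: per-year life years, QALYs, and healthcare costs."""
    if spec.horizon == 0:
        return ScenarioOutput(
            label=spec.label, years=np.arange(0), life_years=np.zeros(0), qalys=np.zeros(0),
            disease_costs=np.zeros(0), unrelated_costs=np.zeros(0),
        )
    engine = CohortEngine(params, population, horizon=spec.horizon)
    return engine.scenario_output(spec)


def diff_scenarios(pedometer: ScenarioOutput, current: ScenarioOutput) -> IncrementalStreams:
    """Element-wise incremental streams between two simulated scenarios."""
    if len(pedometer.years) != len(current.years):
        raise ValueError("scenario outputs must cover the same horizon")
    return IncrementalStreams(
        years=pedometer.years.copy(),
        d_life_years=pedometer.life_years - current.life_years,
        d_qalys=pedometer.qalys - current.qalys,
        d_disease_costs=pedometer.disease_costs - current.disease_costs,
        d_unrelated_costs=pedometer.unrelated_costs - current.unrelated_costs,
    )
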