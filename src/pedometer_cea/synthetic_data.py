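"""Synthetic survey records, population tables, and epidemiological parameters.

The downstream analysis needs three inputs that are not publicly deposited:
lifestyle-survey microdata with daily walking minutes and weekly active days,
a population table of GP visitors by age and sex, and an age-sex-specific
epidemiological parameter set for five chronic diseases. This module
generates statistical stand-ins with the structure the analysis assumes:

* survey records whose physical-activity class distribution is calibrated to
  approximately 17% inactive / 27% insufficiently active / 56% norm active;
* a population table summing exactly to a configured total;
* an internally consistent parameter set (age-increasing incidence,
  prevalences obtained by running the incidence/mortality recursion from age
  20, physical-activity and comorbidity relative risks, utilities, costs).

Nothing here reproduces real Dutch survey distributions or vital statistics;
see the methods note for what these stand-ins do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .disease_model import SEXES, EpiParameters
from .effect_translation import classify_active_days

__all__ = [
    "SurveyConfig",
    "SyntheticEpiConfig",
    "DiseaseSpec",
    "CalibrationError",
    "generate_survey",
    "generate_population",
    "generate_epi_params",
    "write_survey_csv",
    "write_population_csv",
]


class CalibrationError(RuntimeError):
    """The survey generator cannot reach the target class distribution."""

    def __init__(self, achieved, target, tolerance) -> None:
        self.achieved = tuple(achieved)
        super().__init__(
            f"calibration failed: achieved class distribution {np.round(achieved, 4)} "
            f"vs target {tuple(target)} (tolerance {tolerance})"
        )


@dataclass(frozen=True)
class SurveyConfig:
    """Distributional settings of the survey generator.

    Daily walking minutes are gamma distributed (right-skewed, positive);
    weekly active days are binomial on 7 days with a success probability that
    is a logistic function of walking minutes, which induces the positive
    walking/activity association. The logistic intercept is calibrated by a
    one-dimensional search so the expected class distribution matches
    ``target_distribution``; shape, scale and slope are design constants
    chosen so that the calibrated optimum lies within tolerance.
    """

    age_range: tuple[int, int] = (20, 65)
    walking_shape: float = 1.2
    walking_scale: float = 30.0
    activity_slope: float = 0.2
    target_distribution: tuple[float, float, float] = (0.17, 0.27, 0.56)
    tolerance: float = 0.02
    calibration_min_n: int = 5000

    def __post_init__(self) -> None:
        if self.walking_shape <= 0 or self.walking_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if abs(sum(self.target_distribution) - 1) > 1e-9:
            raise ValueError("target_distribution must sum to 1")


def _expected_class_probs(walking: np.ndarray, intercept: float, slope: float) -> np.ndarray:
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * walking)))
    p_inactive = np.mean((1.0 - p) ** 7)
    p_norm = np.mean(stats.binom.sf(4, 7, p))
    return np.array([p_inactive, 1.0 - p_inactive - p_norm, p_norm])


def generate_survey(n: int, seed: int, config: SurveyConfig | None = None) -> pd.DataFrame:
    """Generate ``n`` survey records (age, sex, walking_minutes, active_days).

    Reproducible under a fixed seed. The logistic intercept is calibrated on
    the drawn walking minutes so the *expected* class distribution matches the
    configured target; a :class:`CalibrationError` is raised when the optimum
    misses the target by more than the tolerance (checked for samples of at
    least ``calibration_min_n`` records, below which sampling noise dominates).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or SurveyConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    sex = rng.choice(SEXES, size=n)
    walking = rng.gamma(config.walking_shape, config.walking_scale, size=n)

    def objective(a: float) -> float:
        probs = _expected_class_probs(walking, a, config.activity_slope)
        return float(np.max(np.abs(probs - config.target_distribution)))

    res = optimize.minimize_scalar(objective, bounds=(-30.0, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    intercept = float(res.x)
    achieved = _expected_class_probs(walking, intercept, config.activity_slope)
    if n >= config.calibration_min_n and np.max(np.abs(achieved - config.target_distribution)) > config.tolerance:
        raise CalibrationError(achieved, config.target_distribution, config.tolerance)
    p = 1.0 / (1.0 + np.exp(-(intercept + config.activity_slope * walking)))
    active_days = rng.binomial(7, p)
    return pd.DataFrame(
        {"age": age, "sex": sex, "walking_minutes": walking, "active_days": active_days}
    )


def generate_population(total: int, age_range: tuple[int, int] = (20, 65), seed: int = 0) -> pd.DataFrame:
    """Population table of (age, sex, count) summing exactly to ``total``.

    Persons are allocated uniformly over single-year age classes and the two
    sexes by a multinomial draw, so cell counts vary stochastically around the
    uniform expectation but always sum to the requested total.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    cells = [(a, s) for a in ages for s in SEXES]
    if total == 0:
        counts = np.zeros(len(cells), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(total, np.full(len(cells), 1.0 / len(cells)))
    return pd.DataFrame(
        {"age": [a for a, _ in cells], "sex": [s for _, s in cells], "count": counts}
    )


# ---------------------------------------------------------------------------
# synthetic epidemiological parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseSpec:
    """Shape parameters of one synthetic disease.

    Incidence follows ``base_rate * exp(age_slope * (age - 20))`` per sex
    (scaled by ``sex_ratio`` for females); excess mortality and annual cost
    are constants. Relative risks are per PA class (norm active = 1).
    """

    name: str
    base_rate: float
    age_slope: float
    sex_ratio: float  # female rate = male rate * sex_ratio
    excess_mortality: float
    rr_inactive: float
    rr_insufficient: float
    utility: float
    annual_cost: float
    female_only: bool = False


_DEFAULT_DISEASES = (
    DiseaseSpec("diabetes", 5.0e-4, 0.045, 0.9, 0.006, 1.6, 1.25, 0.85, 2000.0),
    DiseaseSpec("myocardial_infarction", 2.0e-4, 0.055, 0.5, 0.020, 1.8, 1.35, 0.80, 3000.0),
    DiseaseSpec("stroke", 1.5e-4, 0.060, 0.8, 0.030, 1.7, 1.30, 0.70, 5000.0),
    DiseaseSpec("colorectal_cancer", 5.0e-5, 0.070, 0.8, 0.050, 1.4, 1.15, 0.75, 10000.0),
    DiseaseSpec("breast_cancer", 4.0e-4, 0.030, 1.0, 0.030, 1.2, 1.10, 0.75, 8000.0, female_only=True),
)

_DEFAULT_COMORBIDITY = {
    ("myocardial_infarction", "diabetes"): 2.0,
    ("stroke", "diabetes"): 1.8,
    ("stroke", "myocardial_infarction"): 1.5,
}


@dataclass(frozen=True)
class SyntheticEpiConfig:
    """Configuration of the synthetic epidemiological parameter set."""

    diseases: tuple[DiseaseSpec, ...] = _DEFAULT_DISEASES
    comorbidity: dict[tuple[str, str], float] = field(default_factory=lambda: dict(_DEFAULT_COMORBIDITY))
    age_range: tuple[int, int] = (20, 100)
    # Gompertz-like other-cause mortality: base * exp(slope * (age - 20))
    mortality_base: float = 1.0e-4
    mortality_slope: float = 0.095
    # per-capita unrelated care cost: base * exp(slope * (age - 20)) EUR/year
    unrelated_cost_base: float = 1000.0
    unrelated_cost_slope: float = 0.03
    # disease-free reference utility declines linearly with age
    reference_utility_at_20: float = 0.95
    reference_utility_at_100: float = 0.75
    null_mode: bool = False  # all PA relative risks 1, zero utility decrements
    seed: int = 0


def generate_epi_params(config: SyntheticEpiConfig | None = None) -> EpiParameters:
    """Build an internally consistent synthetic :class:`EpiParameters` set.

    Incidence rises exponentially with age; baseline prevalence at each age is
    obtained by running the marginal incidence/mortality recursion from age 20
    (so prevalences, incidences and mortalities cohere); in ``null_mode`` all
    PA relative risks are 1 and utility decrements are zero, which makes the
    intervention inert end-to-end.
    """
    config = config or SyntheticEpiConfig()
    lo, hi = config.age_range
    ages = np.arange(lo, hi + 1)
    A = len(ages)
    names = tuple(d.name for d in config.diseases)
    D = len(names)
    rel_age = ages - lo

    other_mortality = np.tile(
        (config.mortality_base * np.exp(config.mortality_slope * rel_age))[:, None], (1, 2))
    unrelated_cost = np.tile(
        (config.unrelated_cost_base * np.exp(config.unrelated_cost_slope * rel_age))[:, None], (1, 2))
    ref_u = np.tile(
        np.interp(ages, [lo, hi], [config.reference_utility_at_20, config.reference_utility_at_100])[:, None],
        (1, 2))

    incidence = np.zeros((D, A, 2))
    excess = np.zeros((D, A, 2))
    cost = np.zeros((D, A, 2))
    rr_pa = np.ones((D, 3))
    utility = np.ones(D)
    for i, d in enumerate(config.diseases):
        inc_m = d.base_rate * np.exp(d.age_slope * rel_age)
        incidence[i, :, 0] = 0.0 if d.female_only else inc_m
        incidence[i, :, 1] = inc_m * d.sex_ratio
        excess[i, :, 0] = 0.0 if d.female_only else d.excess_mortality
        excess[i, :, 1] = d.excess_mortality
        cost[i, :, 0] = 0.0 if d.female_only else d.annual_cost
        cost[i, :, 1] = d.annual_cost
        if not config.null_mode:
            rr_pa[i] = (d.rr_inactive, d.rr_insufficient, 1.0)
            utility[i] = d.utility
    if np.any(incidence > 1.0) or np.any(excess > 1.0):
        raise ValueError("synthetic rates exceed 1 per annual cycle; adjust shape parameters")

    rr_c = np.ones((D, D))
    for (dis, com), rr in config.comorbidity.items():
        rr_c[names.index(dis), names.index(com)] = rr

    # marginal prevalence recursion from age 20: survivors' disease share after
    # one cycle of incidence among the healthy and differential mortality
    prevalence = np.zeros((D, A, 2))
    for i in range(D):
        for s in range(2):
            p = 0.0
            for ai in range(A):
                prevalence[i, ai, s] = p
                surv_sick = p * np.exp(-(other_mortality[ai, s] + excess[i, ai, s]))
                inc_prob = 1.0 - np.exp(-incidence[i, ai, s])
                surv_well = (1.0 - p) * np.exp(-other_mortality[ai, s])
                new_sick = surv_well * inc_prob
                alive = surv_sick + surv_well
                p = (surv_sick + new_sick) / alive if alive > 0 else 0.0

    return EpiParameters(
        diseases=names,
        ages=ages,
        incidence=incidence,
        excess_mortality=excess,
        prevalence=prevalence,
        rr_pa=rr_pa,
        rr_comorbidity=rr_c,
        utility=utility,
        disease_cost=cost,
        unrelated_cost=unrelated_cost,
        other_mortality=other_mortality,
        reference_utility=ref_u,
    )


def null_epi_config(**overrides) -> SyntheticEpiConfig:
    """Convenience: the default synthetic config with the intervention made inert."""
    return replace(SyntheticEpiConfig(), null_mode=True, **overrides)


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------

def write_survey_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write survey records (age, sex, walking_minutes, active_days, pa_class)."""
    from .effect_translation import PAClass

    out = records.copy()
    out["pa_class"] = [PAClass(c).name.lower() for c in classify_active_days(out["active_days"])]
    out.to_csv(path, index=False)


def write_population_csv(population: pd.DataFrame, path: str | Path) -> None:
    population.to_csv(path, index=False)
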