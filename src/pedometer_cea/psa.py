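"""Probabilistic sensitivity analysis: parameter distributions, Monte-Carlo
re-runs of the pipeline, and cost-effectiveness acceptability curves.

Uncertain parameters and their distributions:

* participation fractions — beta distributions fitted to a stated mean and
  95% interval (the mean is matched exactly; the interval by a 1-D search);
* the SQUASH scoring cost — ``2.22 * (1 + 4*X)`` with X beta-distributed,
  spanning one minute of digital scoring to five minutes of manual scoring;
* the one-year step effect — normal from its meta-analytic 95% CI;
* the sustained-effect fraction — beta;
* disease incidence / prevalence / excess-mortality rates — Poisson and
  binomial resampling around the point rates, with a shared per-disease
  random substream so the three rate types of one disease move together.

Each run redraws every parameter, rebuilds the cascade, the class shift and
the cohort model, and records discounted incremental costs and effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cascade import CascadeParams, UnitCosts
from .disease_model import EpiParameters
from .economics import DiscountRates
from .effect_translation import DownwardShiftError, EffectParams, ShiftInfeasibleError

__all__ = [
    "BetaFit",
    "FitQualityWarning",
    "Table2Distributions",
    "PSAResults",
    "fit_beta",
    "sample_squash_cost",
    "sample_normal_ci",
    "sample_epi",
    "run_psa",
    "ceac",
    "summarize",
]

#: two-sided 95% normal quantile used to recover a standard deviation from a CI
Z95 = 1.9600


class FitQualityWarning(UserWarning):
    """A fitted distribution misses its target quantiles by more than tolerance."""


@dataclass(frozen=True)
class BetaFit:
    alpha: float
    beta: float
    mean: float
    q025: float
    q975: float

    def rvs(self, rng: np.random.Generator, size=None):
        return stats.beta.rvs(self.alpha, self.beta, size=size, random_state=rng)


def fit_beta(mean: float, ci_low: float, ci_high: float, tolerance: float = 0.02) -> BetaFit:
    """Fit a beta distribution to a mean and 95% interval.

    The mean constraint is imposed exactly (``beta = alpha*(1-mean)/mean``);
    ``alpha`` minimizes the squared error of the 2.5% and 97.5% quantiles
    against the stated interval. Emits :class:`FitQualityWarning` when the
    fitted quantiles miss the targets by more than ``tolerance``.
    """
    if not 0 < ci_low < mean < ci_high < 1:
        raise ValueError("need 0 < ci_low < mean < ci_high < 1")

    def objective(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        b = a * (1.0 - mean) / mean
        q = stats.beta.ppf([0.025, 0.975], a, b)
        return float((q[0] - ci_low) ** 2 + (q[1] - ci_high) ** 2)

    res = optimize.minimize_scalar(objective, bounds=(np.log(1e-3), np.log(1e4)),
                                   method="bounded", options={"xatol": 1e-12})
    alpha = float(np.exp(res.x))
    beta = alpha * (1.0 - mean) / mean
    q025, q975 = stats.beta.ppf([0.025, 0.975], alpha, beta)
    if max(abs(q025 - ci_low), abs(q975 - ci_high)) > tolerance:
        warnings.warn(
            f"beta fit for mean {mean} CI ({ci_low}, {ci_high}) achieves quantiles "
            f"({q025:.4f}, {q975:.4f}); outside tolerance {tolerance}",
            FitQualityWarning,
        )
    return BetaFit(alpha=alpha, beta=beta, mean=mean, q025=float(q025), q975=float(q975))


# scaled SQUASH-scoring cost: EUR 2.22 per minute, 1 + 4*X minutes
_SQUASH_BASE = 2.22
_SQUASH_SPAN = 4.0
_squash_beta = None


def _squash_fit() -> BetaFit:
    global _squash_beta
    if _squash_beta is None:
        _squash_beta = fit_beta(0.5, 0.13, 0.87)
    return _squash_beta


def squash_cost_from_x(x: float) -> float:
    """SQUASH scoring cost at beta draw ``x``: 2.22 * (1 + 4x) EUR."""
    return _SQUASH_BASE * (1.0 + _SQUASH_SPAN * x)


def sample_squash_cost(rng: np.random.Generator, size=None):
    """Draw the SQUASH scoring cost (mean 6.66 EUR, 95% interval ~3.37-9.95)."""
    x = _squash_fit().rvs(rng, size=size)
    if size is None:
        return squash_cost_from_x(float(x))
    return _SQUASH_BASE * (1.0 + _SQUASH_SPAN * x)


def sample_normal_ci(mean: float, ci_low: float, ci_high: float, rng: np.random.Generator,
                     truncate_at_zero: bool = False, size=None):
    """Draw from a normal distribution specified by mean and 95% CI.

    The standard deviation is ``(ci_high - ci_low) / (2 * 1.9600)``. Draws are
    untruncated by default; with ``truncate_at_zero`` negative draws are
    redrawn (scalar mode only).
    """
    sd = (ci_high - ci_low) / (2.0 * Z95)
    if size is not None:
        return rng.normal(mean, sd, size=size)
    while True:
        v = float(rng.normal(mean, sd))
        if not truncate_at_zero or v >= 0:
            return v


def sample_epi(params: EpiParameters, rng: np.random.Generator, *,
               incidence_exposure: float = 1e5, prevalence_n: int = 10_000,
               mortality_exposure: float = 1e4, couple: bool = True) -> EpiParameters:
    """Resample disease rates as Poisson counts and prevalences as binomial.

    Each rate is treated as observed over a finite exposure: incidence and
    excess-mortality rates become Poisson counts over their exposure
    (person-years) re-normalized, prevalences binomial proportions out of
    ``prevalence_n``. With ``couple=True`` the three rate types of one disease
    share a single uniform draw (a per-disease substream), making them
    rank-correlated as dependent parameters; with ``couple=False`` each rate
    type of each disease gets an independent draw.
    """
    D = params.n_diseases

    def u_for(d: int, slot: int) -> float:
        if couple:
            return u_disease[d]
        return float(rng.uniform())

    u_disease = rng.uniform(size=D)
    incidence = np.empty_like(params.incidence)
    excess = np.empty_like(params.excess_mortality)
    prevalence = np.empty_like(params.prevalence)
    for d in range(D):
        u = u_for(d, 0)
        incidence[d] = stats.poisson.ppf(u, params.incidence[d] * incidence_exposure) / incidence_exposure
        u = u_for(d, 1)
        excess[d] = stats.poisson.ppf(u, params.excess_mortality[d] * mortality_exposure) / mortality_exposure
        u = u_for(d, 2)
        prevalence[d] = stats.binom.ppf(u, prevalence_n, params.prevalence[d]) / prevalence_n
    return EpiParameters(
        diseases=params.diseases,
        ages=params.ages,
        incidence=incidence,
        excess_mortality=excess,
        prevalence=prevalence,
        rr_pa=params.rr_pa,
        rr_comorbidity=params.rr_comorbidity,
        utility=params.utility,
        disease_cost=params.disease_cost,
        unrelated_cost=params.unrelated_cost,
        other_mortality=params.other_mortality,
        reference_utility=params.reference_utility,
        utility_combination=params.utility_combination,
    )


@dataclass(frozen=True)
class Table2Distributions:
    """Fitted distributions of the uncertain cascade/effect parameters."""

    f_gp: BetaFit = field(default_factory=lambda: fit_beta(0.375, 0.056, 0.789))
    f_squash: BetaFit = field(default_factory=lambda: fit_beta(0.83, 0.54, 0.99))
    f_accept: BetaFit = field(default_factory=lambda: fit_beta(0.50, 0.13, 0.87))
    maintenance: BetaFit = field(default_factory=lambda: fit_beta(0.25, 0.08, 0.47))
    steps_mean: float = 2491.0
    steps_ci: tuple[float, float] = (1098.0, 3885.0)


@dataclass
class ParameterDraw:
    """One realized parameter set for a pipeline evaluation."""

    f_gp: float
    f_squash: float
    c_scoring: float
    f_accept: float
    f_followup: float
    steps: float
    maintenance: float

    def cascade_params(self, base: CascadeParams) -> CascadeParams:
        return CascadeParams(
            base_population=base.base_population, f_gp=self.f_gp, f_squash=self.f_squash,
            f_target=base.f_target, f_accept=self.f_accept, f_followup=self.f_followup,
        )

    def unit_costs(self, base: UnitCosts) -> UnitCosts:
        return UnitCosts(
            c_approach=base.c_approach, c_scoring=self.c_scoring,
            c_counseling=base.c_counseling, c_pedometer=base.c_pedometer,
            c_followup=base.c_followup,
        )

    def effect_params(self, base: EffectParams) -> EffectParams:
        return EffectParams(steps_effect_1yr=self.steps, step_pace=base.step_pace,
                            maintenance_fraction=self.maintenance)


def draw_parameters(rng: np.random.Generator, dists: Table2Distributions) -> ParameterDraw:
    """Draw one joint parameter set (fractions, costs, effect sizes)."""
    return ParameterDraw(
        f_gp=float(dists.f_gp.rvs(rng)),
        f_squash=float(dists.f_squash.rvs(rng)),
        c_scoring=sample_squash_cost(rng),
        f_accept=float(dists.f_accept.rvs(rng)),
        f_followup=float(dists.f_accept.rvs(rng)),
        steps=sample_normal_ci(dists.steps_mean, *dists.steps_ci, rng),
        maintenance=float(dists.maintenance.rvs(rng)),
    )


def degenerate_draw(dists: Table2Distributions | None = None) -> ParameterDraw:
    """All distributions collapsed to their means (reproduces the base case)."""
    dists = dists or Table2Distributions()
    return ParameterDraw(
        f_gp=dists.f_gp.mean, f_squash=dists.f_squash.mean,
        c_scoring=squash_cost_from_x(0.5),
        f_accept=dists.f_accept.mean, f_followup=dists.f_accept.mean,
        steps=dists.steps_mean, maintenance=dists.maintenance.mean,
    )


@dataclass
class PSAResults:
    """Per-run incremental outcomes plus the parameter draws that produced them."""

    runs: pd.DataFrame  # columns: draw parameters, delta_ly, delta_qaly, intervention_cost,
    #                     future_cost_incl/excl, total_cost_incl/excl
    seed: int
    n_redraws: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def run_psa(n_runs: int, seed: int, config=None, *, pipeline_inputs=None,
            degenerate: bool = False, epi_uncertainty: bool = True,
            couple_epi: bool = True, max_redraw_factor: int = 100) -> PSAResults:
    """Monte-Carlo re-evaluation of the whole pipeline.

    Draws all uncertain parameters, rebuilds cascade, class shift and cohort
    model for each run, and records discounted incremental outcomes.
    Deterministic given ``seed``. Runs whose draws are unusable (non-positive
    step effect, or a walking-minute shift larger than the survey supports)
    are redrawn and counted in ``n_redraws``.

    ``pipeline_inputs`` (a :class:`pedometer_cea.pipeline.PipelineInputs`) may
    be supplied to reuse survey, population and base epidemiology; otherwise
    they are generated from ``config`` (default configuration when ``None``).
    """
    from . import pipeline as pl  # runtime import to avoid a cycle

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    inputs = pipeline_inputs if pipeline_inputs is not None else pl.build_inputs(config, seed=seed)
    cfg = inputs.config
    dists = Table2Distributions()
    rng = np.random.default_rng(seed)
    base_engine = inputs.engine  # reused when epidemiology is not resampled
    rows = []
    n_redraws = 0
    max_attempts = max_redraw_factor * n_runs
    for _ in range(n_runs):
        while True:
            if degenerate:
                draw = degenerate_draw(dists)
                epi = inputs.epi
            else:
                draw = draw_parameters(rng, dists)
                epi = sample_epi(
                    inputs.epi, rng,
                    incidence_exposure=cfg.psa.incidence_exposure,
                    prevalence_n=cfg.psa.prevalence_n,
                    mortality_exposure=cfg.psa.mortality_exposure,
                    couple=couple_epi,
                ) if epi_uncertainty else inputs.epi
            if draw.steps <= 0:
                n_redraws += 1
                max_attempts -= 1
                if max_attempts <= 0:
                    raise RuntimeError("PSA redraw budget exhausted")
                continue
            try:
                engine = base_engine if epi is inputs.epi else None
                ce = pl.evaluate_pipeline(inputs, draw.cascade_params(inputs.cascade_params),
                                          draw.unit_costs(inputs.unit_costs),
                                          draw.effect_params(inputs.effect_params),
                                          epi=epi, engine=engine)
            except (ShiftInfeasibleError, DownwardShiftError):
                n_redraws += 1
                max_attempts -= 1
                if max_attempts <= 0:
                    raise RuntimeError("PSA redraw budget exhausted")
                continue
            break
        rows.append({
            "f_gp": draw.f_gp, "f_squash": draw.f_squash, "c_scoring": draw.c_scoring,
            "f_accept": draw.f_accept, "f_followup": draw.f_followup,
            "steps": draw.steps, "maintenance": draw.maintenance,
            "delta_ly": ce.delta_ly, "delta_qaly": ce.delta_qaly,
            "intervention_cost": ce.intervention_cost,
            "future_cost_incl": ce.future_cost_diff_included,
            "future_cost_excl": ce.future_cost_diff_excluded,
            "total_cost_incl": ce.total_cost_diff_included,
            "total_cost_excl": ce.total_cost_diff_excluded,
        })
    return PSAResults(runs=pd.DataFrame(rows), seed=seed, n_redraws=n_redraws)


def ceac(results: PSAResults, lambdas=None, *, included_costs: bool = True) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    The probability at each threshold is the fraction of runs with positive
    net monetary benefit, ``lambda * dQALY - dCost > 0``.
    """
    if lambdas is None:
        lambdas = np.arange(0, 50_001, 1_000)
    lam = np.asarray(lambdas, dtype=float)
    dq = results.runs["delta_qaly"].to_numpy()
    dc = results.runs["total_cost_incl" if included_costs else "total_cost_excl"].to_numpy()
    prob = [(l * dq - dc > 0).mean() for l in lam]
    return pd.DataFrame({"lambda": lam, "probability": prob})


def _mean_ci(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)),
            "p2.5": float(np.percentile(x, 2.5)),
            "p97.5": float(np.percentile(x, 97.5))}


def summarize(results: PSAResults) -> dict:
    """Means with 2.5-97.5 percentile intervals, plus ICER summaries.

    ICERs are summarized as the ratio of mean costs to mean effects (the
    standard CEA convention; the per-run ICER distribution is heavily skewed,
    so the mean of ratios is reported only as a diagnostic).
    """
    r = results.runs
    out = {
        "n_runs": results.n_runs,
        "n_redraws": results.n_redraws,
        "life_years": _mean_ci(r["delta_ly"].to_numpy()),
        "qalys": _mean_ci(r["delta_qaly"].to_numpy()),
        "intervention_cost": _mean_ci(r["intervention_cost"].to_numpy()),
        "future_cost_diff": {
            "included": _mean_ci(r["future_cost_incl"].to_numpy()),
            "excluded": _mean_ci(r["future_cost_excl"].to_numpy()),
        },
        "total_cost_diff": {
            "included": _mean_ci(r["total_cost_incl"].to_numpy()),
            "excluded": _mean_ci(r["total_cost_excl"].to_numpy()),
        },
    }
    for variant in ("incl", "excl"):
        cost_mean = r[f"total_cost_{variant}"].mean()
        out[f"icer_per_qaly_{variant}"] = float(cost_mean / r["delta_qaly"].mean())
        out[f"icer_per_ly_{variant}"] = float(cost_mean / r["delta_ly"].mean())
    valid = r["delta_qaly"] > 0
    per_run = (r.loc[valid, "total_cost_incl"] / r.loc[valid, "delta_qaly"]).to_numpy()
    if per_run.size:
        out["icer_per_qaly_mean_of_ratios"] = float(np.mean(per_run))
        out["icer_per_qaly_median_of_ratios"] = float(np.median(per_run))
    return out


def plot_ce_plane(results: PSAResults, path) -> None:
    """Scatter of incremental costs vs incremental QALYs (included costs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(results.runs["delta_qaly"], results.runs["total_cost_incl"] / 1e6, s=4, alpha=0.4)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental costs (million EUR)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["lambda"], table["probability"])
    ax.set_xlabel("Willingness to pay (EUR per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
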