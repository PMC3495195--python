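# Methods

This note documents the model implemented in `pedometer_cea`, its
assumptions, the synthetic data it runs on by default, and the numerical
conventions chosen where the design was genuinely open.

## The decision problem

A one-off primary-care screening wave: general practitioners identify
insufficiently active adult patients (via the SQUASH questionnaire), counsel
them, and offer a pedometer with an electronic diary plus three follow-up
sessions. The comparator is current practice (no action). The evaluation
takes a healthcare perspective, in 2009 euros, with outcomes in life years
(LY) and quality-adjusted life years (QALYs).

## Intervention cascade (`cascade`)

Participation narrows through five stages with fractions
(f_gp, f_squash, f_target, f_accept, f_followup) = (0.375, 0.83, 0.441,
0.50, 0.50) applied to 7.27 million GP visitors aged 20–65. Unit costs per
stage: EUR 0.66 (approach), 6.66 (SQUASH scoring), 22.20 (counseling),
19.95 (pedometer), 19.80 (follow-up sessions).

Two conventions are load-bearing and were chosen because they are the only
pair that reproduces every published count *and* cost cell simultaneously:

1. **Exact counts are unrounded chained products**; a *display* rounding
   (nearest 1,000 at or above one million, nearest 100 below; ties to even)
   is applied per stage for reporting.
2. **Stage costs are billed on display counts**, e.g.
   0.66 × 2,726,000 = 1,799,160.

The deterministic total intervention cost is the exact sum of the five
stage costs, EUR 53,917,275.

## Step effect and class shift (`effect_translation`)

The pedometer raises activity by 2491 steps/day after one year (meta-
analytic pooled estimate, 95% CI 1098–3885). At a pace of 106 steps/minute
this is 23.5 minutes/day. Only a fraction of the effect is sustained:
the default maintenance fraction 0.25 (95% CI 0.08–0.47) gives 623
steps/day ≈ 5.88 minutes/day, applied as a constant from year 1 onward for
the remaining lifetime.

**Display convention.** Whole-minute figures are reported by rounding to
the nearest integer with exact .5 ties rounded *down* (23.5 → 23,
5.877 → 6). A single rule covering both published figures was preferred to
separate truncation/nearest conventions.

**Shift derivation.** Physical activity is classified per the Dutch
guideline: 0 active days/week → inactive, 1–4 → insufficiently active,
≥5 → norm active. The class shift achieved by walking δ minutes/day more is
derived from survey records, separately for the <55 and ≥55 age strata
(the guideline defines "moderate" differently by age): the subgroup of
records with walking minutes above a threshold is selected — threshold
found by bisection on the monotone subgroup-mean function — such that the
subgroup's mean daily walking exceeds the stratum mean by δ; the shift is
the subgroup's class distribution minus the stratum's. The threshold
construction is the simplest monotone selection rule consistent with
"a subgroup walking δ minutes more on average"; with finite data the
subgroup mean is a step function of the threshold, so the candidate
closest to the target mean is taken. Requesting a δ beyond the data's
support raises an error carrying the maximum achievable δ.

**Transitions.** Net class shifts are converted to individual upward moves
by minimal transport along the chain inactive → insufficient → norm:
inactive outflow first covers the insufficient class's net gain, the
remainder goes straight to norm active, and any residual norm-active gain
comes from insufficient → norm movers. Only upward movement is modelled; a
shift implying downward movement is rejected. Completers are split across
the two age strata in proportion to each stratum's not-norm-active
population, and each stratum's movers are spread over its age–sex cells in
proportion to cell population.

## Cohort disease model (`disease_model`)

A discrete-time Markov cohort model in the tradition of national
chronic-disease models. Cohorts are stratified by sex, one-year age class
(20–100) and physical-activity class, and occupy the 2^5 = 32 disease-set
compartments of {diabetes, myocardial infarction, stroke, colorectal
cancer, breast cancer}, plus death. Joint disease-set tracking (rather
than marginal prevalences) makes comorbidity dependence exact: the
incidence of disease *d* is multiplied by RR_pa(d, class) and by the
product of comorbidity relative risks of the diseases already present.
Mortality is other-cause plus the sum of present diseases' excess rates.

Cycle order and conventions (standard state-transition practice; chosen
once and fixed):

* rates convert to annual probabilities as 1 − exp(−rate), which keeps
  probabilities in [0, 1] by construction;
* mortality is applied first, then acquisitions (independent across
  absent diseases within a cycle), then age increments;
* person-years use the half-cycle correction (mean of start and end
  occupancy); cohorts exit after living through age 100;
* QALY weights multiply the age–sex reference utility by the product of
  the present diseases' utility weights (an additive-decrement variant is
  selectable via `utility_combination`);
* costs per cycle are Σ prevalent-disease annual costs plus per-capita
  unrelated-care cost times alive person-years. "Costs in life years
  gained" are exactly the incremental unrelated-care costs, so the
  excluded-variant cost stream is the incremental disease-cost stream.

The physical-activity class is fixed over a lifetime; scenarios differ only
in the initial class allocation (current practice vs the post-intervention
allocation implied by the mover counts). Because the dynamics are linear in
cohort mass, the engine simulates each (sex, class, starting-age) cohort
once at unit mass; scenario outputs are mass-weighted sums, and
*incremental* streams are computed in flow form — mover mass times the
difference between destination-class and source-class unit streams. This
makes the null case (all PA relative risks 1) give incremental streams that
are exactly 0.0 in floating point, not merely small.

## Economics (`economics`)

Differential discounting per the Dutch pharmacoeconomic guidelines: effects
at 1.5%/year, costs at 4.0%/year, end-of-year convention, with the one-off
intervention cost undiscounted at t = 0. ICER = incremental cost /
incremental effect, defined only in the trade-off quadrant; cheaper-and-
more-effective is flagged dominant, costlier-and-less-effective dominated.
EUR amounts are display-rounded to the nearest 100 for reporting only.

## Probabilistic sensitivity analysis (`psa`)

Uncertain parameters and distributions:

| parameter | distribution | mean | 95% CI |
|---|---|---|---|
| fraction participating GPs | beta | 0.375 | 0.056–0.789 |
| fraction filling in SQUASH | beta | 0.83 | 0.54–0.99 |
| SQUASH scoring cost | 2.22·(1+4·beta) | 6.66 | 3.37–9.95 |
| fraction accepting pedometer; fraction completing follow-up | beta | 0.50 | 0.13–0.87 |
| additional steps/day | normal | 2491 | 1098–3885 |
| fraction sustained long-term | beta | 0.25 | 0.08–0.47 |
| disease rates | Poisson / binomial | — | — |

Beta distributions are fitted with the mean constrained exactly
(β = α(1−m)/m) and α chosen by a bounded 1-D search minimizing the squared
error of the 2.5%/97.5% quantiles; all four rows fit within ±0.005. The
normal's SD is recovered as (CI width)/(2·1.9600). Disease incidence and
excess-mortality rates are resampled as Poisson counts over finite
exposures (defaults: 10^5 and 10^4 person-years) and prevalences as
binomial proportions (n = 10^4); the three rate types of one disease share
a single uniform draw (a per-disease substream), making them rank-
correlated as dependent parameters — the coupling mechanism of the original
analysis is not documented, and this shared-substream construction is the
declared stand-in. Cells within one rate type share the draw too
(systematic rather than cell-level uncertainty). Draws producing unusable
parameters (non-positive step effect, or a walking shift beyond the
survey's support) are redrawn, not clipped, and counted.

Each run rebuilds cascade, shift and cohort model and records discounted
incremental outcomes. Summaries report means with 2.5–97.5 percentile
intervals; the ICER is summarized as the ratio of mean costs to mean
effects (the per-run ratio distribution is heavily right-skewed, so the
mean of ratios is exposed only as a diagnostic). The CEAC reports, per
willingness-to-pay λ, the fraction of runs with λ·ΔQALY − ΔC > 0.

## Synthetic data (`synthetic_data`)

No public microdata or calibrated national parameter set exists, so the
package generates stand-ins:

* **Survey records**: walking minutes ~ Gamma(shape 1.2, scale 30) — a
  right-skewed positive distribution with mean 36 min/day of commuting plus
  leisure walking; active days ~ Binomial(7, logistic(a + 0.2·walking)).
  The slope/shape constants were fixed by a one-off design exploration; the
  intercept *a* is calibrated per sample by a bounded 1-D search so the
  expected class distribution matches (0.17, 0.27, 0.56) — the national
  distribution the analysis assumes — within ±0.02 (checked for n ≥ 5,000,
  below which sampling noise dominates; an unreachable target raises a
  calibration error naming the achieved distribution).
* **Population**: a multinomial allocation of the configured total
  (default 7.27M, ages 20–65, both sexes) over uniform cells; totals are
  exact by construction.
* **Epidemiology**: incidence rates base·exp(slope·(age−20)) per disease
  and sex with literature-plausible PA relative risks (inactive 1.2–1.8,
  insufficient 1.1–1.35, norm 1.0), constant excess mortality and annual
  cost per disease, comorbidity relative risks (diabetes→MI 2.0,
  diabetes→stroke 1.8, MI→stroke 1.5), Gompertz-like other-cause mortality,
  age-increasing unrelated-care costs, and an age-declining reference
  utility. Baseline prevalence is *derived* by running the marginal
  incidence/mortality recursion from age 20, so the parameter set is
  internally consistent. Breast cancer is female-only. A null mode sets all
  PA relative risks to 1 and utility decrements to 0, making the
  intervention inert end-to-end.

**What the synthetic defaults do and do not show.** They reproduce the
*structure* the analysis assumes (class distribution, age gradients,
comorbidity and activity relative risks, skewed walking distribution), so
passing tests demonstrate the pipeline's correctness and its qualitative
behaviour (positive health gains, cost offsets, skewed ICER distribution,
monotone response to the sustained-effect fraction). They do not reproduce
Dutch vital statistics or the calibrated national disease model, so
absolute outputs (e.g. QALYs gained, the base-case ICER) are properties of
the synthetic configuration, not estimates for the Netherlands. Under the
default synthetic set the disease-cost offsets are larger relative to the
unrelated-care costs than in the original Dutch calibration, so the
synthetic base case lands near cost-neutrality.

## Problem sizes and numerics

Default runs use 10,000 survey records, the full 7.27M population (cohort
mass is free — the engine is deterministic), an 81-year horizon, and 1,000
PSA runs in the acceptance script (the PSA run count is configurable; the
full analysis convention is 100,000). Tolerances: shift components sum to
zero within 1e-12; mass conservation holds within 1e-9 over the full
horizon; closed-form checks (exponential survival, discounted annuity) hold
within 1e-9. Ties in display rounding follow round-half-to-even for person
counts and EUR amounts, and round-half-down for minutes.

## Known limitations

* The threshold rule for the "walks δ minutes more" subgroup is one of
  several defensible constructions (matching or reweighting would differ).
* Physical-activity class does not drift with age in either scenario; the
  original description hints at aging-related drift in current practice but
  does not specify a mechanism, so the hook is off by default.
* Acquisitions within a cycle are independent given the start-of-cycle
  state; multi-disease acquisition in one year is slightly underweighted
  relative to a continuous-time formulation.
* No disease remission, no risk factors other than physical activity, no
  societal-perspective costs.
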