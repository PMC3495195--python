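"""Translate a pedometer step effect into a shift over physical-activity classes.

The intervention effect is expressed as additional steps per day. This module
converts steps to minutes of daily walking, attenuates the one-year effect to a
sustained long-term effect, derives the implied shift over the three Dutch
physical-activity guideline classes from survey records, and converts the net
shift into individual upward transitions (mover counts).

Physical-activity classes follow the Dutch guideline: *norm active* means at
least 30 minutes of at-least-moderate activity on five or more days per week;
*insufficiently active* means one to four such days; *inactive* means none.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PAClass",
    "PAClassDistribution",
    "EffectParams",
    "ShiftVector",
    "StratumShift",
    "TransitionCounts",
    "classify_active_days",
    "class_distribution",
    "steps_to_minutes",
    "display_minutes",
    "long_term_steps",
    "derive_shift",
    "transition_counts",
    "ShiftInfeasibleError",
    "DownwardShiftError",
]

#: steps walked per minute at an average walking pace
DEFAULT_STEP_PACE = 106.0


class PAClass(enum.IntEnum):
    """Physical-activity class per the Dutch guideline."""

    INACTIVE = 0
    INSUFFICIENTLY_ACTIVE = 1
    NORM_ACTIVE = 2


@dataclass(frozen=True)
class EffectParams:
    """Pedometer effect size and its long-term attenuation.

    Parameters
    ----------
    steps_effect_1yr:
        Additional steps per day after one year of pedometer use (meta-analytic
        pooled estimate, default 2491).
    step_pace:
        Steps per minute of walking (default 106).
    maintenance_fraction:
        Fraction of the one-year effect sustained in the long term
        (default 0.25).
    """

    steps_effect_1yr: float = 2491.0
    step_pace: float = DEFAULT_STEP_PACE
    maintenance_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.steps_effect_1yr <= 0:
            raise ValueError("steps_effect_1yr must be > 0")
        if self.step_pace <= 0:
            raise ValueError("step_pace must be > 0")
        if not 0 < self.maintenance_fraction <= 1:
            raise ValueError("maintenance_fraction must be in (0, 1]")

    def long_term_minutes(self) -> float:
        """Exact sustained daily walking minutes implied by the parameters."""
        return steps_to_minutes(
            long_term_steps(self.steps_effect_1yr, self.maintenance_fraction),
            self.step_pace,
        )


class PAClassDistribution:
    """Proportions over the three physical-activity classes.

    Order: (inactive, insufficiently active, norm active). Must sum to 1.
    """

    __slots__ = ("proportions",)

    def __init__(self, proportions) -> None:
        p = np.asarray(proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("need exactly three class proportions")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
        self.proportions = p

    def __getitem__(self, cls: PAClass) -> float:
        return float(self.proportions[int(cls)])

    def __repr__(self) -> str:  # pragma: no cover
        i, s, n = self.proportions
        return f"PAClassDistribution(inactive={i:.4f}, insufficient={s:.4f}, norm={n:.4f})"


def classify_active_days(active_days) -> np.ndarray:
    """Map days/week with >=30 min moderate activity to PA classes.

    0 days -> inactive, 1-4 days -> insufficiently active, >=5 -> norm active.
    """
    d = np.asarray(active_days)
    if np.any(d < 0) or np.any(d > 7):
        raise ValueError("active_days must be within 0..7")
    return np.where(d == 0, PAClass.INACTIVE, np.where(d >= 5, PAClass.NORM_ACTIVE, PAClass.INSUFFICIENTLY_ACTIVE))


def class_distribution(active_days) -> PAClassDistribution:
    """Empirical PA-class distribution of a set of records."""
    cls = classify_active_days(active_days)
    counts = np.bincount(cls, minlength=3).astype(float)
    return PAClassDistribution(counts / counts.sum())


# ---------------------------------------------------------------------------
# step / minute conversions
# ---------------------------------------------------------------------------

def steps_to_minutes(steps: float, pace: float = DEFAULT_STEP_PACE) -> float:
    """Convert steps/day to walking minutes/day at the given pace.

    Returns the exact real quotient; use :func:`display_minutes` for the
    whole-minute reporting convention.
    """
    if pace <= 0:
        raise ValueError("pace must be > 0")
    return steps / pace


def display_minutes(minutes: float) -> int:
    """Whole-minute reporting convention: nearest integer, ties rounded down.

    23.5 displays as 23; 5.877 displays as 6.
    """
    return int(math.ceil(minutes - 0.5))


def long_term_steps(steps_1yr: float, fraction: float) -> int:
    """Sustained long-term step effect: fraction of the one-year effect.

    Rounded to the nearest whole step (2491 steps at 25% -> 623 steps).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return round(fraction * steps_1yr)


# ---------------------------------------------------------------------------
# shift derivation from survey records
# ---------------------------------------------------------------------------

class ShiftInfeasibleError(ValueError):
    """No walking-minute threshold can raise the subgroup mean by delta."""

    def __init__(self, stratum: str, delta: float, max_delta: float) -> None:
        self.max_achievable_delta = max_delta
        super().__init__(
            f"stratum {stratum!r}: requested delta {delta:.3f} min/day exceeds the "
            f"maximum achievable {max_delta:.3f} min/day for these records"
        )


@dataclass(frozen=True)
class StratumShift:
    """Shift over PA classes for one age stratum."""

    stratum: str
    shift: np.ndarray  # signed per-class differences, sums to 0
    baseline: PAClassDistribution
    subgroup: PAClassDistribution
    threshold: float  # walking-minute cut defining the subgroup
    achieved_delta: float  # subgroup mean minus stratum mean, min/day
    n_records: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.shift))) > 1e-12:
            raise ValueError("per-stratum shift components must sum to 0")


@dataclass(frozen=True)
class ShiftVector:
    """Per-stratum shifts over the PA classes (strata: below / at-or-above the age split)."""

    strata: dict[str, StratumShift]
    age_split: int

    def __iter__(self):
        return iter(self.strata.values())


def _stratum_shift(name: str, walking: np.ndarray, days: np.ndarray, delta: float) -> StratumShift:
    """Threshold construction for one stratum.

    The subgroup is {records with walking_minutes >= t}. Its mean walking time
    is non-decreasing in t, so the threshold achieving a target mean of
    (stratum mean + delta) is found by bisection over the sorted unique
    walking values; the candidate with subgroup mean closest to the target is
    taken (the subgroup mean is a step function of t, so exact equality is
    generally unattainable on finite data).
    """
    mean_all = float(walking.mean())
    target = mean_all + delta
    order = np.argsort(walking, kind="stable")
    w_sorted = walking[order]
    d_sorted = days[order]
    # suffix means: mean of walking among records >= each candidate threshold
    suffix_sum = np.cumsum(w_sorted[::-1])[::-1]
    n = len(w_sorted)
    counts = n - np.arange(n)
    suffix_mean = suffix_sum / counts
    # candidate thresholds are positions where a new unique value starts
    starts = np.flatnonzero(np.r_[True, w_sorted[1:] != w_sorted[:-1]])
    cand_means = suffix_mean[starts]  # non-decreasing
    if target > cand_means[-1] + 1e-12:
        raise ShiftInfeasibleError(name, delta, cand_means[-1] - mean_all)
    # bisection on the monotone step function, then closest-mean tie-break
    j = int(np.searchsorted(cand_means, target, side="left"))
    best = starts[j]
    if j > 0 and abs(cand_means[j - 1] - target) <= abs(cand_means[j] - target):
        best = starts[j - 1]
    sub_days = d_sorted[best:]
    baseline = class_distribution(days)
    subgroup = class_distribution(sub_days)
    shift = subgroup.proportions - baseline.proportions
    return StratumShift(
        stratum=name,
        shift=shift,
        baseline=baseline,
        subgroup=subgroup,
        threshold=float(w_sorted[best]),
        achieved_delta=float(suffix_mean[best] - mean_all),
        n_records=n,
    )


def derive_shift(records: pd.DataFrame, delta_minutes: float, age_split: int = 55) -> ShiftVector:
    """Derive the PA-class shift implied by walking ``delta_minutes`` more per day.

    For each age stratum (below / at-or-above ``age_split``) the subgroup of
    records walking at least a threshold number of minutes is chosen so that
    its mean daily walking time exceeds the stratum mean by ``delta_minutes``.
    The shift is the subgroup's class distribution minus the stratum's.

    Parameters
    ----------
    records:
        DataFrame with columns ``age``, ``walking_minutes``, ``active_days``.
    delta_minutes:
        Extra daily walking minutes the subgroup must average (>= 0).
    age_split:
        Stratum boundary in years (default 55; "moderate" activity is defined
        differently below and above this age in the Dutch guideline).
    """
    if delta_minutes < 0:
        raise ValueError("delta_minutes must be >= 0")
    strata = {}
    for name, mask in [
        (f"<{age_split}", records["age"].to_numpy() < age_split),
        (f">={age_split}", records["age"].to_numpy() >= age_split),
    ]:
        sub = records.loc[mask]
        if len(sub) == 0:
            raise ValueError(f"age stratum {name} contains no records")
        if delta_minutes == 0:
            baseline = class_distribution(sub["active_days"].to_numpy())
            strata[name] = StratumShift(
                stratum=name,
                shift=np.zeros(3),
                baseline=baseline,
                subgroup=baseline,
                threshold=float(sub["walking_minutes"].min()),
                achieved_delta=0.0,
                n_records=len(sub),
            )
        else:
            strata[name] = _stratum_shift(
                name,
                sub["walking_minutes"].to_numpy(dtype=float),
                sub["active_days"].to_numpy(),
                delta_minutes,
            )
    return ShiftVector(strata=strata, age_split=age_split)


# ---------------------------------------------------------------------------
# net shift -> individual upward transitions
# ---------------------------------------------------------------------------

class DownwardShiftError(ValueError):
    """The shift implies downward class movement, outside the model scope."""


def _display_round_100(x: float) -> int:
    return int(round(x / 100.0)) * 100


@dataclass(frozen=True)
class TransitionCounts:
    """Upward PA-class transitions among intervention completers.

    Exact (real-valued) mover counts plus the nearest-100 display values.
    """

    inactive_to_insufficient: float
    inactive_to_norm: float
    insufficient_to_norm: float
    unchanged: float
    display: dict[str, int] = field(default_factory=dict)

    @property
    def movers(self) -> float:
        return self.inactive_to_insufficient + self.inactive_to_norm + self.insufficient_to_norm

    @property
    def completers(self) -> float:
        return self.movers + self.unchanged


def transition_counts(shift: np.ndarray, baseline: PAClassDistribution, completers: float) -> TransitionCounts:
    """Convert a net class shift into mover counts by minimal upward transport.

    Mass leaving the inactive class first fills the insufficient class's net
    gain; the remainder moves straight to norm active; any further norm-active
    gain is covered by insufficient -> norm movers. This is the minimal-mover
    solution on the inactive -> insufficient -> norm chain.
    """
    s = np.asarray(shift, dtype=float)
    if s.shape != (3,):
        raise ValueError("shift must have three components")
    if abs(s.sum()) > 1e-9:
        raise ValueError("shift components must sum to 0")
    if completers < 0:
        raise ValueError("completers must be >= 0")
    d_inact, d_insuf, d_norm = s
    if d_norm < -1e-12 or d_inact > 1e-12:
        raise DownwardShiftError(
            f"shift {tuple(np.round(s, 6))} implies downward movement; only upward "
            "transitions are modelled"
        )
    if baseline[PAClass.INACTIVE] + d_inact < -1e-9 or baseline[PAClass.INSUFFICIENTLY_ACTIVE] + d_insuf < -1e-9:
        raise ValueError("shift removes more mass than the baseline class holds")
    loss_inactive = -d_inact * completers
    gain_norm = max(d_norm, 0.0) * completers
    x1 = min(loss_inactive, max(d_insuf, 0.0) * completers)  # inactive -> insufficient
    x2 = loss_inactive - x1                                  # inactive -> norm
    x3 = gain_norm - x2                                      # insufficient -> norm
    if x3 < -1e-9:
        raise DownwardShiftError("transport infeasible: norm-active gain smaller than inactive outflow")
    x3 = max(x3, 0.0)
    unchanged = completers - (x1 + x2 + x3)
    display = {
        "inactive_to_insufficient": _display_round_100(x1),
        "inactive_to_norm": _display_round_100(x2),
        "insufficient_to_norm": _display_round_100(x3),
        "unchanged": _display_round_100(unchanged),
    }
    return TransitionCounts(
        inactive_to_insufficient=x1,
        inactive_to_norm=x2,
        insufficient_to_norm=x3,
        unchanged=unchanged,
        display=display,
    )
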