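"""Discounting, incremental cost-effectiveness ratios, and net monetary benefit.

Dutch pharmacoeconomic guidelines prescribe differential discounting: health
effects at 1.5% per year and costs at 4.0% per year. Intervention costs
accrue undiscounted at t=0 (the screening wave is one-off); model streams
start in year 1 and are discounted end-of-year, consistent with the
half-cycle person-year convention of the cohort model.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .disease_model import IncrementalStreams

__all__ = [
    "DiscountRates",
    "Dominance",
    "CEResult",
    "discount_stream",
    "icer",
    "display_eur",
    "net_monetary_benefit",
    "ce_result_from_streams",
]


@dataclass(frozen=True)
class DiscountRates:
    """Annual discount rates: effects at 1.5%, costs at 4.0% by default."""

    effects_rate: float = 0.015
    costs_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.effects_rate < 0 or self.costs_rate < 0:
            raise ValueError("discount rates must be >= 0")


def discount_stream(stream, rate: float, start_year: int = 0) -> float:
    """Present value of a per-year stream: sum of value_t / (1+rate)^t.

    ``start_year`` is the calendar year of the stream's first element relative
    to the intervention year t=0; cohort-model streams start at
    ``start_year=1``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    s = np.asarray(stream, dtype=float)
    t = np.arange(start_year, start_year + len(s))
    return float(np.sum(s / (1.0 + rate) ** t))


class Dominance(enum.Enum):
    TRADEOFF = "tradeoff"
    DOMINANT = "dominant"      # more effect, lower (or equal) cost
    DOMINATED = "dominated"    # less (or equal) effect, higher (or equal) cost
    UNDEFINED = "undefined"    # zero effect difference, nonzero cost difference


def icer(delta_cost: float, delta_effect: float) -> tuple[float | None, Dominance]:
    """Incremental cost-effectiveness ratio with dominance handling.

    Returns ``(ratio, flag)``; the ratio is ``None`` outside the trade-off
    quadrant (north-east: positive incremental cost and effect).
    """
    if delta_effect > 0 and delta_cost > 0:
        return delta_cost / delta_effect, Dominance.TRADEOFF
    if delta_effect > 0:  # at most as costly, more effective
        return None, Dominance.DOMINANT
    if delta_effect == 0:
        return (None, Dominance.UNDEFINED) if delta_cost != 0 else (None, Dominance.DOMINANT)
    # delta_effect < 0
    if delta_cost >= 0:
        return None, Dominance.DOMINATED
    return None, Dominance.TRADEOFF  # south-west quadrant: saving at a health loss


def display_eur(value: float) -> int:
    """Reporting convention for EUR amounts: nearest 100 (ties to even)."""
    return int(round(value / 100.0)) * 100


def net_monetary_benefit(lam: float, delta_effect: float, delta_cost: float) -> float:
    """NMB = lambda * incremental effect - incremental cost."""
    return lam * delta_effect - delta_cost


@dataclass
class CEResult:
    """Discounted incremental outcomes of the pedometer scenario.

    Costs are reported both including and excluding unrelated healthcare costs
    incurred in life years gained; ICERs use the included variant unless noted.
    """

    delta_ly: float
    delta_qaly: float
    intervention_cost: float
    future_cost_diff_included: float
    future_cost_diff_excluded: float
    total_cost_diff_included: float
    total_cost_diff_excluded: float
    icer_per_ly_included: float | None
    icer_per_qaly_included: float | None
    icer_per_ly_excluded: float | None
    icer_per_qaly_excluded: float | None
    dominance: str

    def display(self) -> dict:
        """Publication-shaped dict with nearest-100-EUR ICERs."""
        fmt = lambda v: None if v is None else display_eur(v)
        return {
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "intervention_cost": self.intervention_cost,
            "future_cost_diff": {"included": self.future_cost_diff_included,
                                 "excluded": self.future_cost_diff_excluded},
            "total_cost_diff": {"included": self.total_cost_diff_included,
                                "excluded": self.total_cost_diff_excluded},
            "icer_per_ly": {"included": fmt(self.icer_per_ly_included),
                            "excluded": fmt(self.icer_per_ly_excluded)},
            "icer_per_qaly": {"included": fmt(self.icer_per_qaly_included),
                              "excluded": fmt(self.icer_per_qaly_excluded)},
            "dominance": self.dominance,
        }

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {**asdict(self), **extra}
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def ce_result_from_streams(streams: IncrementalStreams, intervention_cost: float,
                           rates: DiscountRates | None = None) -> CEResult:
    """Aggregate incremental model streams into a discounted CE result.

    Effects are discounted at the effects rate and costs at the costs rate;
    the intervention cost enters undiscounted at t=0.
    """
    rates = rates or DiscountRates()
    d_ly = discount_stream(streams.d_life_years, rates.effects_rate, start_year=1)
    d_qaly = discount_stream(streams.d_qalys, rates.effects_rate, start_year=1)
    fut_incl = discount_stream(streams.d_costs_included, rates.costs_rate, start_year=1)
    fut_excl = discount_stream(streams.d_costs_excluded, rates.costs_rate, start_year=1)
    tot_incl = intervention_cost + fut_incl
    tot_excl = intervention_cost + fut_excl
    per_qaly_incl, dom = icer(tot_incl, d_qaly)
    per_ly_incl, _ = icer(tot_incl, d_ly)
    per_qaly_excl, _ = icer(tot_excl, d_qaly)
    per_ly_excl, _ = icer(tot_excl, d_ly)
    return CEResult(
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        intervention_cost=intervention_cost,
        future_cost_diff_included=fut_incl,
        future_cost_diff_excluded=fut_excl,
        total_cost_diff_included=tot_incl,
        total_cost_diff_excluded=tot_excl,
        icer_per_ly_included=per_ly_incl,
        icer_per_qaly_included=per_qaly_incl,
        icer_per_ly_excluded=per_ly_excl,
        icer_per_qaly_excluded=per_qaly_excl,
        dominance=dom.value,
    )
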