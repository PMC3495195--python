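"""Intervention participation funnel and bottom-up costing.

The pedometer scenario starts from all GP visitors aged 20-65 and narrows
through five stages: visiting a participating GP, completing the SQUASH
physical-activity questionnaire, being identified as not norm-active (the
target population), accepting a pedometer, and completing three follow-up
sessions. Each stage carries a unit cost billed to the persons reaching it.

Exact counts are unrounded chained products of the stage fractions; reported
counts follow a display-rounding convention (nearest 1,000 above one million,
nearest 100 below), and stage costs are billed on the displayed counts —
the only convention that reproduces every published count and cost cell
simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CascadeParams", "UnitCosts", "CascadeStage", "CascadeResult", "display_round", "run_cascade"]


@dataclass(frozen=True)
class CascadeParams:
    """Participation fractions of the intervention funnel.

    Defaults are the base-case values: 7.27 million GP visitors, 37.5% with a
    participating GP, 83% completing the SQUASH, 44.1% not norm-active, 50%
    accepting a pedometer and 50% of those completing follow-up.
    """

    base_population: float = 7_270_000.0
    f_gp: float = 0.375
    f_squash: float = 0.83
    f_target: float = 0.441
    f_accept: float = 0.50
    f_followup: float = 0.50

    def __post_init__(self) -> None:
        if self.base_population < 0:
            raise ValueError("base_population must be >= 0")
        for name in ("f_gp", "f_squash", "f_target", "f_accept", "f_followup"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class UnitCosts:
    """Per-person unit costs (2009 EUR) of each funnel stage.

    approach: one minute of GP-assistant time; scoring: GP scores the SQUASH;
    counseling: ten minutes of GP time; pedometer: device with electronic
    diary; followup: three ten-minute assistant sessions.
    """

    c_approach: float = 0.66
    c_scoring: float = 6.66
    c_counseling: float = 22.20
    c_pedometer: float = 19.95
    c_followup: float = 19.80

    def __post_init__(self) -> None:
        for name in ("c_approach", "c_scoring", "c_counseling", "c_pedometer", "c_followup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CascadeStage:
    name: str
    exact_count: float
    display_count: int
    unit_cost: float
    stage_cost: float


@dataclass(frozen=True)
class CascadeResult:
    """Ordered funnel stages with exact/display counts, stage costs, and the total."""

    stages: tuple[CascadeStage, ...]
    total_cost: float

    def __getitem__(self, name: str) -> CascadeStage:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(name)

    @property
    def completers_exact(self) -> float:
        return self.stages[-1].exact_count

    @property
    def completers_display(self) -> int:
        return self.stages[-1].display_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "exact_count": [s.exact_count for s in self.stages],
                "display_count": [s.display_count for s in self.stages],
                "unit_cost": [s.unit_cost for s in self.stages],
                "stage_cost": [s.stage_cost for s in self.stages],
            }
        )


def display_round(count: float) -> int:
    """Reporting convention for person counts.

    Counts of one million or more round to the nearest 1,000 (ties to even);
    smaller counts round to the nearest 100.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count >= 1_000_000:
        return round(count / 1000.0) * 1000
    return round(count / 100.0) * 100


_STAGES = (
    # (name, fraction attribute, unit-cost attribute)
    ("base_population", None, None),
    ("visiting_participating_gp", "f_gp", "c_approach"),
    ("screened_with_squash", "f_squash", "c_scoring"),
    ("target_population", "f_target", "c_counseling"),
    ("receiving_pedometer", "f_accept", "c_pedometer"),
    ("completing_followup", "f_followup", "c_followup"),
)


def run_cascade(params: CascadeParams, costs: UnitCosts | None = None) -> CascadeResult:
    """Run the participation funnel and bill each stage's unit cost.

    Exact counts chain the unrounded products; each stage's cost is its unit
    cost times the *displayed* count of persons reaching that stage.
    """
    costs = costs or UnitCosts()
    stages: list[CascadeStage] = []
    exact = params.base_population
    for name, frac_attr, cost_attr in _STAGES:
        if frac_attr is not None:
            exact = exact * getattr(params, frac_attr)
        disp = display_round(exact)
        unit = getattr(costs, cost_attr) if cost_attr else 0.0
        stages.append(
            CascadeStage(
                name=name,
                exact_count=exact,
                display_count=disp,
                unit_cost=unit,
                stage_cost=unit * disp,
            )
        )
    total = sum(s.stage_cost for s in stages)
    return CascadeResult(stages=tuple(stages), total_cost=total)
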