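"""Ten-year cardiovascular risk profiles and their cost consequences.

Each arm of the programme has a 10-year absolute risk (in percent, with a
standard error) of four cardiovascular outcomes — CHD, fatal CHD, stroke,
fatal stroke — for each sex, produced upstream by a risk engine for type-2
diabetes (the packaged fixture carries published engine output; any callable
honouring the same contract can be plugged in instead).

From a comparator/intervention pair this module derives:

* the absolute risk reduction ARR = risk_c - risk_i (percentage points),
* the mortality reduction ratio rr_m = risk_i / risk_c, which downstream
  scales cardiovascular mortality in the intervention life table, and
* the cost consequence: incremental cost per 1 percentage-point ARR.

Risks are stored in percent throughout, matching how they are reported;
conversion to proportions happens only inside the life-table module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from typing import Callable, Iterable, Mapping, Sequence

from .costing import CostComparison

__all__ = [
    "OUTCOMES",
    "FATAL_OUTCOMES",
    "SEXES",
    "ARMS",
    "RiskProfile",
    "RiskEngineInput",
    "RiskReduction",
    "CostConsequence",
    "RiskError",
    "weight_profile",
    "absolute_risk_reduction",
    "cost_consequence",
    "risk_source",
    "reduction_grid",
]

OUTCOMES = ("CHD", "fatal_CHD", "stroke", "fatal_stroke")
FATAL_OUTCOMES = ("fatal_CHD", "fatal_stroke")
SEXES = ("male", "female")
ARMS = ("intervention", "comparator")


class RiskError(ValueError):
    """Raised on invalid risk inputs or inconsistent profile pairs."""


@dataclass(frozen=True)
class RiskProfile:
    """10-year absolute risk of one outcome, one sex, one arm (percent)."""

    arm: str
    outcome: str
    sex: str
    mean_risk: float  # percent
    se: float = 0.0  # percent

    def __post_init__(self):
        if self.arm not in ARMS:
            raise RiskError(f"unknown arm {self.arm!r}")
        if self.outcome not in OUTCOMES:
            raise RiskError(f"unknown outcome {self.outcome!r}")
        if self.sex not in SEXES:
            raise RiskError(f"unknown sex {self.sex!r}")
        if not 0.0 <= self.mean_risk <= 100.0:
            raise RiskError(f"mean_risk must be in [0, 100] percent, got {self.mean_risk}")
        if self.se < 0:
            raise RiskError("standard error must be non-negative")


@dataclass(frozen=True)
class RiskEngineInput:
    """Cohort-level inputs a 10-year CVD risk engine consumes.

    Physiologic ranges are enforced loosely; the point is to catch unit
    mistakes (e.g. HbA1c in mmol/mol where percent is expected), not to
    adjudicate clinical plausibility.
    """

    mean_age: float
    ethnicity: str
    smoking_status: str
    diabetes_duration: float
    hba1c: float  # percent
    sbp: float  # mmHg
    total_cholesterol: float  # mmol/L
    hdl: float  # mmol/L

    def __post_init__(self):
        checks = [
            ("mean_age", self.mean_age, 18, 100),
            ("diabetes_duration", self.diabetes_duration, 0, 80),
            ("hba1c", self.hba1c, 3, 20),
            ("sbp", self.sbp, 60, 260),
            ("total_cholesterol", self.total_cholesterol, 1, 15),
            ("hdl", self.hdl, 0.3, 5),
        ]
        for name, v, lo, hi in checks:
            if not lo <= v <= hi:
                raise RiskError(f"{name}={v} outside physiologic range [{lo}, {hi}]")


def weight_profile(
    subgroup_risks: Sequence[tuple[float, float, float]],
) -> tuple[float, float]:
    """Collapse subgroup risks (mean, se, weight) into one weighted profile.

    Demographic weighting (sex, ethnicity, smoking status) uses the weighted
    arithmetic mean of the subgroup risks.  The pooled SE is
    sqrt(sum w_i * se_i**2) with weights normalised to sum to one; this
    variance-weighted rule is one defensible choice among several and is
    isolated here so it can be swapped.
    """
    if not subgroup_risks:
        raise RiskError("at least one subgroup required")
    weights = [w for _, _, w in subgroup_risks]
    if any(w < 0 for w in weights):
        raise RiskError("weights must be non-negative")
    wsum = sum(weights)
    if wsum == 0:
        raise RiskError("weights must not all be zero")
    w = [wi / wsum for wi in weights]
    mean = sum(wi * m for (m, _, _), wi in zip(subgroup_risks, w))
    se = math.sqrt(sum(wi * s * s for (_, s, _), wi in zip(subgroup_risks, w)))
    return mean, se


@dataclass(frozen=True)
class RiskReduction:
    """Effect of the intervention on one outcome/sex.

    ``arr`` is in percentage points (comparator minus intervention);
    ``rr_m`` is the intervention:comparator risk ratio used to scale CVD
    mortality rates.  The two are consistent by construction:
    arr = risk_c * (1 - rr_m).
    """

    outcome: str
    sex: str
    arr: float
    rr_m: float


def absolute_risk_reduction(comp: RiskProfile, intv: RiskProfile) -> RiskReduction:
    """ARR and mortality reduction ratio from a comparator/intervention pair."""
    if comp.arm != "comparator" or intv.arm != "intervention":
        raise RiskError("expected (comparator, intervention) profiles in that order")
    if (comp.outcome, comp.sex) != (intv.outcome, intv.sex):
        raise RiskError(
            f"mismatched profiles: {comp.outcome}/{comp.sex} vs {intv.outcome}/{intv.sex}"
        )
    if comp.mean_risk == 0:
        raise RiskError("comparator risk is zero; mortality ratio undefined")
    return RiskReduction(
        outcome=comp.outcome,
        sex=comp.sex,
        arr=comp.mean_risk - intv.mean_risk,
        rr_m=intv.mean_risk / comp.mean_risk,
    )


@dataclass(frozen=True)
class CostConsequence:
    """Incremental cost per 1 percentage-point absolute risk reduction."""

    outcome: str
    sex: str
    cost_per_pct_arr: float  # ZAR


def cost_consequence(cc: CostComparison, rr: RiskReduction) -> CostConsequence:
    """Incremental cost divided by the absolute risk reduction."""
    if rr.arr <= 0:
        raise RiskError(
            f"intervention is not risk-reducing for {rr.outcome}/{rr.sex} (arr={rr.arr})"
        )
    return CostConsequence(
        outcome=rr.outcome,
        sex=rr.sex,
        cost_per_pct_arr=float(cc.diff_total) / rr.arr,
    )


RiskEngine = Callable[[], Iterable[RiskProfile]]


def risk_source(engine: RiskEngine) -> dict[tuple[str, str, str], RiskProfile]:
    """Materialise a complete risk grid from a pluggable engine.

    The engine is any zero-argument callable yielding RiskProfile objects
    (the packaged fixture engine returns published values; a user-supplied
    adapter around an external risk-engine implementation works the same
    way).  The result must cover all 2 arms x 4 outcomes x 2 sexes = 16
    cells exactly once.
    """
    grid: dict[tuple[str, str, str], RiskProfile] = {}
    for p in engine():
        key = (p.arm, p.outcome, p.sex)
        if key in grid:
            raise RiskError(f"duplicate risk profile for {key}")
        grid[key] = p
    expected = {(a, o, s) for a in ARMS for o in OUTCOMES for s in SEXES}
    missing = expected - set(grid)
    if missing:
        raise RiskError(f"incomplete risk grid; missing {sorted(missing)}")
    return grid


def reduction_grid(
    grid: Mapping[tuple[str, str, str], RiskProfile],
    outcomes: Sequence[str] = OUTCOMES,
) -> dict[tuple[str, str], RiskReduction]:
    """Absolute risk reductions for every outcome/sex cell of a risk grid."""
    out = {}
    for outcome in outcomes:
        for sex in SEXES:
            comp = grid[("comparator", outcome, sex)]
            intv = grid[("intervention", outcome, sex)]
            out[(outcome, sex)] = absolute_risk_reduction(comp, intv)
    return out
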