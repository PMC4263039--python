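"""End-to-end evaluation: one joint parameter vector in, (cost, LYG, ICER) out.

This is the glue the probabilistic sensitivity analysis re-runs on every
bootstrap draw.  A parameter vector (per-capita arm costs, 10-year fatal
CHD/stroke risks per arm and sex, diabetic hazard ratios) is pushed through:

1. incremental per-capita cost = cost_intervention - cost_comparator;
2. mortality reduction ratios per sex and cause,
   rr = risk_intervention / risk_comparator (fatal CHD -> IHD,
   fatal stroke -> stroke);
3. per sex: decompose the all-cause schedule, inflate CVD mortality by the
   diabetic hazard ratios, scale the intervention arm's CVD mortality by
   the cause-specific ratios, and build paired abridged life tables;
4. life-years gained and national aggregation, then the ICER.

Evaluating the closure at the parameter means gives the deterministic point
estimate; the same closure under joint draws gives the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import cea
from .cea import CEAError, EffectPair, national_projection
from .costing import CostComparison, CostModel, build_cost_model, compare_costs
from .lifetable import (
    HazardRatioSet,
    LifeTable,
    MortalitySchedule,
    apply_intervention,
    build_life_table,
    decompose_mortality,
    diabetic_cvd_mortality,
    life_years_gained,
)
from .risk_effects import SEXES

__all__ = [
    "SexSplit",
    "PipelineInputs",
    "make_pipeline_model",
    "evaluate_point",
    "param_means",
    "sex_life_tables",
    "PointEstimate",
]

#: Share of the per-band diabetic population assigned to each sex when the
#: population input is not sex-specific.
SexSplit = {"male": 0.5, "female": 0.5}


@dataclass(frozen=True)
class PipelineInputs:
    """Fixed (non-sampled) inputs of the evaluation.

    schedules : general-population mortality schedule per sex.
    population_by_band : diabetic population counts per age band (summed
        over sexes; split by ``SexSplit`` internally).
    strategy : national LYG aggregation strategy (see
        :func:`capicea.cea.national_projection`).
    """

    schedules: Mapping[str, MortalitySchedule]
    population_by_band: np.ndarray
    strategy: str = "per_band_delta_e"

    def sex_population(self, sex: str) -> np.ndarray:
        return np.asarray(self.population_by_band, dtype=float) * SexSplit[sex]


def sex_life_tables(
    schedule: MortalitySchedule,
    hr: HazardRatioSet,
    rr_chd: float,
    rr_stroke: float,
    radix: float,
) -> tuple[LifeTable, LifeTable]:
    """(comparator, intervention) life tables for one sex.

    The comparator population experiences diabetic CVD mortality; the
    intervention population has each CVD cause scaled by its mortality
    reduction ratio.  Other-cause mortality is identical in both arms.
    """
    diabetic = diabetic_cvd_mortality(decompose_mortality(schedule), hr)
    reduced = apply_intervention(diabetic, rr_chd, rr_stroke)
    comp_lt = build_life_table(diabetic.m_total, radix, schedule.bands, schedule.sex)
    intv_lt = build_life_table(reduced.m_total, radix, schedule.bands, schedule.sex)
    return comp_lt, intv_lt


def _evaluate(inputs: PipelineInputs, draw: Mapping[str, float]):
    i_cost = draw["cost_intervention"]
    c_cost = draw["cost_comparator"]
    d_cost = i_cost - c_cost
    hr = HazardRatioSet(
        rr_fatal_chd_male=draw["hr_fatal_chd_male"],
        rr_fatal_chd_female=draw["hr_fatal_chd_female"],
        rr_fatal_stroke_male=draw["hr_fatal_stroke_male"],
        rr_fatal_stroke_female=draw["hr_fatal_stroke_female"],
    )
    tables: dict[str, tuple[LifeTable, LifeTable]] = {}
    lyg_per_capita: dict[str, float] = {}
    delta_e: dict[str, np.ndarray] = {}
    rr_by_sex: dict[str, tuple[float, float]] = {}
    for sex in SEXES:
        rr_chd = (
            draw[f"risk_fatal_chd_{sex}_intervention"]
            / draw[f"risk_fatal_chd_{sex}_comparator"]
        )
        rr_stroke = (
            draw[f"risk_fatal_stroke_{sex}_intervention"]
            / draw[f"risk_fatal_stroke_{sex}_comparator"]
        )
        rr_by_sex[sex] = (rr_chd, rr_stroke)
        pop = inputs.sex_population(sex)
        radix = float(pop[0]) if pop[0] > 0 else 1.0
        comp_lt, intv_lt = sex_life_tables(
            inputs.schedules[sex], hr, rr_chd, rr_stroke, radix
        )
        tables[sex] = (comp_lt, intv_lt)
        lyg, de = life_years_gained(intv_lt, comp_lt)
        lyg_per_capita[sex] = lyg / radix
        delta_e[sex] = de

    national_lyg = 0.0
    national_cost = 0.0
    for sex in SEXES:
        pop = inputs.sex_population(sex)
        cost_cmp = _cost_comparison_from(d_cost)
        n_cost, n_lyg = national_projection(
            cost_cmp,
            pop,
            strategy=inputs.strategy,
            delta_e_by_band=delta_e[sex],
            per_capita_lyg=lyg_per_capita[sex],
        )
        national_cost += n_cost
        national_lyg += n_lyg
    return d_cost, national_cost, national_lyg, tables, lyg_per_capita, rr_by_sex


def _cost_comparison_from(d_cost: float) -> CostComparison:
    """Minimal cost comparison carrying an arbitrary total difference.

    The bootstrap draws arm totals directly (component structure is not
    sampled), so a synthetic single-component pair carries the difference
    into :func:`national_projection`.
    """
    base = 1000.0
    comp = build_cost_model(
        "comparator",
        {
            "compensation": base,
            "training": 0,
            "investigations": 0,
            "medication_consumables": 0,
            "overheads": 0,
        },
    )
    intv = build_cost_model(
        "intervention",
        {
            "compensation": round(base + d_cost, 2),
            "training": 0,
            "investigations": 0,
            "medication_consumables": 0,
            "overheads": 0,
        },
    )
    return compare_costs(intv, comp)


def make_pipeline_model(inputs: PipelineInputs) -> cea.PipelineModel:
    """Closure mapping one joint draw to (incremental cost, LYG, ICER).

    The incremental cost entering the ICER is national (per-capita
    difference times population), matched with national LYG; the ratio
    equals the per-capita ICER whenever the LYG strategy is per-capita
    scaling.
    """

    def model(draw: Mapping[str, float]) -> tuple[float, float, float]:
        _, national_cost, national_lyg, *_ = _evaluate(inputs, draw)
        if national_lyg == 0:
            return national_cost, 0.0, float("nan")
        icer_val = cea.icer(national_cost, 0.0, EffectPair(national_lyg, 0.0))
        return national_cost, national_lyg, icer_val

    return model


def param_means(params) -> dict[str, float]:
    """The degenerate (point) draw: every parameter at its mean."""
    return {p.name: p.mean for p in params}


@dataclass(frozen=True)
class PointEstimate:
    """Deterministic pipeline evaluation at the parameter means."""

    incremental_cost_per_capita: float
    national_cost: float
    national_lyg: float
    icer: float
    lyg_per_capita: dict[str, float]
    rr_by_sex: dict[str, tuple[float, float]]
    tables: dict[str, tuple[LifeTable, LifeTable]]


def evaluate_point(inputs: PipelineInputs, params) -> PointEstimate:
    """Run the pipeline once at the parameter means."""
    draw = param_means(params)
    d_cost, national_cost, national_lyg, tables, lyg_pc, rr = _evaluate(inputs, draw)
    if national_lyg == 0:
        raise CEAError("point estimate has zero life-years gained; ICER undefined")
    return PointEstimate(
        incremental_cost_per_capita=d_cost,
        national_cost=national_cost,
        national_lyg=national_lyg,
        icer=national_cost / national_lyg,
        lyg_per_capita=lyg_pc,
        rr_by_sex=rr,
        tables=tables,
    )
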