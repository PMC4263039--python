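"""Synthetic generators for every pipeline input, plus a brute-force oracle.

The published analysis consumed national age-band mortality schedules
(all-cause, IHD, stroke) and diabetic population counts from a national
burden-of-disease study; those inputs are not printed and cannot ship here.
This module generates replacements with the statistical structure the
analysis assumes, so every stage is testable end-to-end:

* all-cause mortality follows a Gompertz hazard, the standard form for
  adult mortality: M_T(x) = a * exp(b * (x - 25)), evaluated at band
  midpoints; defaults give adult life expectancies of the same magnitude
  as the published tables;
* CVD is a fixed fraction of all-cause mortality, split between IHD and
  stroke; the all-cause baseline is sex-neutral (sex enters downstream
  through sex-specific hazard ratios and risk reductions);
* the diabetic population has a unimodal age distribution over the six
  bands, scaled to a configurable total.

Everything is deterministic given a :class:`SyntheticConfig`; generators
that draw randomness use ``numpy.random.default_rng(seed)``.

The module also provides the designated brute-force oracle for all
abridged-life-table tolerances: a single-year-step life table evaluated on
the same hazard (:func:`single_year_person_years`), and
:func:`recovery_scenario`, which packages inputs whose generating truth
(mortality ratio, cost difference, oracle life-years gained) is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .lifetable import (
    AgeBand,
    HazardRatioSet,
    MortalitySchedule,
    default_bands,
)
from .risk_effects import SEXES, RiskProfile

__all__ = [
    "SyntheticConfig",
    "SyntheticError",
    "gen_mortality_schedule",
    "gen_risk_profiles",
    "gen_population",
    "recovery_scenario",
    "RecoveryScenario",
    "single_year_person_years",
    "DEFAULT_COMPARATOR_RISKS",
    "DEFAULT_ARR",
]

#: Unimodal age-distribution weights over the six default bands, peaking in
#: mid-life like the reported diabetic population.
POPULATION_WEIGHTS = (0.06, 0.17, 0.26, 0.25, 0.17, 0.09)


class SyntheticError(ValueError):
    """Raised on invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic input generators.

    gompertz_a : baseline all-cause hazard at age 25, per person-year.
    gompertz_b : log-hazard slope per year of age.
    cvd_fraction : share of all-cause mortality that is CVD (IHD + stroke).
    ihd_stroke_split : IHD share of CVD mortality.
    population_scale : total diabetic population over all bands (defaults
        to the reported male column total).
    true_rr_m : generating mortality reduction ratio for recovery tests.
    """

    seed: int = 0
    gompertz_a: float = 0.002
    gompertz_b: float = 0.085
    cvd_fraction: float = 0.25
    ihd_stroke_split: float = 0.5
    population_scale: int = 674_075
    true_rr_m: float = 0.7
    bands: tuple[AgeBand, ...] = field(default_factory=default_bands)

    def __post_init__(self):
        if self.gompertz_a <= 0:
            raise SyntheticError("gompertz_a must be positive")
        if not 0 < self.cvd_fraction < 1:
            raise SyntheticError("cvd_fraction must be in (0, 1)")
        if not 0 < self.ihd_stroke_split < 1:
            raise SyntheticError("ihd_stroke_split must be in (0, 1)")
        if self.population_scale <= 0:
            raise SyntheticError("population_scale must be positive")
        if not 0 < self.true_rr_m <= 1:
            raise SyntheticError("true_rr_m must be in (0, 1]")

    def hazard(self, age: float, sex: str = "male") -> float:
        """All-cause Gompertz hazard at an exact age.

        The baseline is sex-neutral: sex differences in the analysis enter
        downstream through sex-specific hazard ratios and risk reductions,
        not through the all-cause schedule.  ``sex`` is accepted for
        interface symmetry.
        """
        del sex
        return self.gompertz_a * np.exp(self.gompertz_b * (age - 25.0))


def gen_mortality_schedule(cfg: SyntheticConfig, sex: str = "male") -> MortalitySchedule:
    """Gompertz all-cause schedule with proportional IHD/stroke components.

    Rates are the hazard evaluated at band midpoints (the open band uses
    its nominal-width centre); they increase strictly with age by
    construction.  Parameter combinations driving any band rate to >= 1
    per person-year are rejected.
    """
    if sex not in SEXES:
        raise SyntheticError(f"unknown sex {sex!r}")
    m_total = np.array([cfg.hazard(b.midpoint, sex) for b in cfg.bands])
    if np.any(m_total >= 1.0):
        raise SyntheticError("Gompertz parameters give a band rate >= 1 per person-year")
    m_ihd = m_total * cfg.cvd_fraction * cfg.ihd_stroke_split
    m_stroke = m_total * cfg.cvd_fraction * (1.0 - cfg.ihd_stroke_split)
    return MortalitySchedule(
        sex=sex, bands=cfg.bands, m_total=m_total, m_ihd=m_ihd, m_stroke=m_stroke
    )


#: Comparator 10-year fatal-event risks (percent) used when none are given;
#: magnitudes follow the published risk grid.
DEFAULT_COMPARATOR_RISKS: dict[tuple[str, str], float] = {
    ("CHD", "male"): 13.05,
    ("CHD", "female"): 7.11,
    ("fatal_CHD", "male"): 8.74,
    ("fatal_CHD", "female"): 4.78,
    ("stroke", "male"): 7.12,
    ("stroke", "female"): 5.05,
    ("fatal_stroke", "male"): 1.13,
    ("fatal_stroke", "female"): 0.82,
}

#: Default generating absolute risk reductions (percentage points).
DEFAULT_ARR: dict[tuple[str, str], float] = {
    ("CHD", "male"): 3.13,
    ("CHD", "female"): 1.75,
    ("fatal_CHD", "male"): 2.68,
    ("fatal_CHD", "female"): 1.50,
    ("stroke", "male"): 0.72,
    ("stroke", "female"): 0.51,
    ("fatal_stroke", "male"): 0.30,
    ("fatal_stroke", "female"): 0.20,
}

SE_FRACTION = 0.10  # SEs default to 10% of the mean risk


def gen_risk_profiles(
    cfg: SyntheticConfig,
    true_arr_map: Mapping[tuple[str, str], float] | None = None,
    comparator_risks: Mapping[tuple[str, str], float] | None = None,
    random: bool = False,
) -> list[RiskProfile]:
    """Full 16-cell risk grid with known generating risk reductions.

    Intervention risk is comparator risk minus the generating ARR, cell by
    cell; SEs are proportional to the means.  With ``random=True`` the
    comparator means are jittered log-normally (10% coefficient of
    variation) under the config seed, reproducibly.
    """
    arr_map = dict(DEFAULT_ARR if true_arr_map is None else true_arr_map)
    comp = dict(DEFAULT_COMPARATOR_RISKS if comparator_risks is None else comparator_risks)
    rng = np.random.default_rng(cfg.seed)
    profiles = []
    for (outcome, sex), c_risk in comp.items():
        if random:
            c_risk = float(c_risk * rng.lognormal(0.0, 0.1))
        if not 0 < c_risk < 100:
            raise SyntheticError(f"comparator risk for {outcome}/{sex} outside (0, 100)")
        arr = arr_map.get((outcome, sex), 0.0)
        if arr > c_risk:
            raise SyntheticError(f"ARR exceeds comparator risk for {outcome}/{sex}")
        i_risk = c_risk - arr
        profiles.append(
            RiskProfile("comparator", outcome, sex, c_risk, SE_FRACTION * c_risk)
        )
        profiles.append(
            RiskProfile("intervention", outcome, sex, i_risk, SE_FRACTION * i_risk)
        )
    return profiles


def gen_population(cfg: SyntheticConfig) -> np.ndarray:
    """Diabetic population counts per age band, summing exactly to scale.

    The unimodal band weights are fixed; integer counts are apportioned by
    largest remainder so the total is exact and deterministic.
    """
    if len(POPULATION_WEIGHTS) != len(cfg.bands):
        raise SyntheticError("population weights defined for the default six bands only")
    target = np.array(POPULATION_WEIGHTS) * cfg.population_scale
    counts = np.floor(target).astype(np.int64)
    short = int(cfg.population_scale - counts.sum())
    order = np.argsort(-(target - counts))
    counts[order[:short]] += 1
    return counts


def single_year_person_years(
    rate_fn: Callable[[float], float],
    start_age: int = 25,
    max_age: int = 130,
    radix: float = 1.0,
) -> float:
    """Cumulative person-years after ``start_age`` by single-year steps.

    The brute-force life-table oracle: one-year intervals with the
    half-interval assumption (q = M / (1 + M/2), L = l - d/2), hazard
    evaluated at mid-year, and a stationary remainder l/M at ``max_age``.
    Abridged tables are tested against this.
    """
    l = float(radix)
    total = 0.0
    for x in range(start_age, max_age):
        m = rate_fn(x + 0.5)
        q = m / (1.0 + 0.5 * m)
        d = l * q
        total += l - 0.5 * d
        l -= d
    total += l / rate_fn(float(max_age))
    return total


@dataclass(frozen=True)
class RecoveryScenario:
    """A complete input bundle plus its generating truth.

    ``oracle_lyg_per_capita`` holds, per sex, the life-years gained per
    cohort member computed by the single-year oracle on the exact Gompertz
    hazard (not the band-midpoint discretisation the pipeline sees), so
    end-to-end agreement demonstrates the abridged table recovers the
    truth, not merely that two identical discretisations agree.
    """

    config: SyntheticConfig
    schedules: dict[str, MortalitySchedule]
    hazard_ratios: HazardRatioSet
    population: np.ndarray
    true_rr_m: float
    cost_difference: float
    oracle_lyg_per_capita: dict[str, float]
    expected_icer: float | None  # None when oracle LYG is zero


#: Central hazard ratios used by recovery scenarios (published values).
RECOVERY_HAZARD_RATIOS = HazardRatioSet(2.03, 2.54, 2.00, 2.04)

RECOVERY_COST_DIFFERENCE = 1003.68  # ZAR per capita per year


def _diabetic_rate_fn(
    cfg: SyntheticConfig, sex: str, hr: HazardRatioSet, rr_m: float
) -> Callable[[float], float]:
    rr_chd, rr_stroke = hr.for_sex(sex)

    def rate(age: float) -> float:
        m = cfg.hazard(age, sex)
        m_ihd = m * cfg.cvd_fraction * cfg.ihd_stroke_split
        m_stroke = m * cfg.cvd_fraction * (1.0 - cfg.ihd_stroke_split)
        m_other = m - m_ihd - m_stroke
        return m_other + rr_m * (rr_chd * m_ihd + rr_stroke * m_stroke)

    return rate


def recovery_scenario(cfg: SyntheticConfig) -> RecoveryScenario:
    """Inputs with known generating truth for parameter-recovery testing.

    The same mortality reduction ratio ``cfg.true_rr_m`` is applied to both
    CVD causes in both the truth computation and (by the caller) the
    pipeline, so the only discrepancy between pipeline output and truth is
    the abridged-table discretisation.
    """
    schedules = {sex: gen_mortality_schedule(cfg, sex) for sex in SEXES}
    hr = RECOVERY_HAZARD_RATIOS
    oracle_lyg = {}
    for sex in SEXES:
        t_comp = single_year_person_years(_diabetic_rate_fn(cfg, sex, hr, 1.0))
        t_intv = single_year_person_years(_diabetic_rate_fn(cfg, sex, hr, cfg.true_rr_m))
        oracle_lyg[sex] = t_intv - t_comp
    mean_lyg = float(np.mean([oracle_lyg[s] for s in SEXES]))
    expected_icer = RECOVERY_COST_DIFFERENCE / mean_lyg if mean_lyg != 0 else None
    return RecoveryScenario(
        config=cfg,
        schedules=schedules,
        hazard_ratios=hr,
        population=gen_population(cfg),
        true_rr_m=cfg.true_rr_m,
        cost_difference=RECOVERY_COST_DIFFERENCE,
        oracle_lyg_per_capita=oracle_lyg,
        expected_icer=expected_icer,
    )
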