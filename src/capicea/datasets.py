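"""Packaged reference datasets.

Small transcriptions of the published input tables ship with the package so
the whole pipeline runs without any download:

* per-arm cost components (annual, per capita, ZAR),
* the 10-year CVD risk grid per arm/outcome/sex with standard errors
  (risk-engine output; treated as data, not code),
* the uncertainty parameters driving the probabilistic sensitivity
  analysis (hazard ratios, fatal-event risks, per-capita costs), and
* the published life-table summary (reported diabetic population per age
  band and the survivors / cumulative person-years / life expectancy
  columns for both arms), used for internal-consistency checks and as the
  population input to national aggregation.

The national age-band mortality schedules behind the published life tables
come from a burden-of-disease study and are not printed anywhere; use
:mod:`capicea.synthetic` to generate statistically comparable schedules.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cea import UncertaintyParameter
from .costing import CostModel, build_cost_model
from .lifetable import HazardRatioSet
from .risk_effects import RiskProfile

__all__ = [
    "load_cost_models",
    "fixture_risk_engine",
    "load_risk_profiles",
    "load_uncertainty_parameters",
    "load_hazard_ratios",
    "load_published_lifetable",
]


def _data(name: str) -> pd.DataFrame:
    with resources.files("capicea.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_cost_models() -> dict[str, CostModel]:
    """Both arms' cost models built from the packaged component table."""
    df = _data("costs.csv")
    out = {}
    for arm, grp in df.groupby("arm"):
        out[arm] = build_cost_model(
            arm, {r.component: str(r.amount_zar) for r in grp.itertuples()}
        )
    return out


def load_risk_profiles() -> list[RiskProfile]:
    """The packaged 16-cell risk grid as a flat list."""
    df = _data("risk_profiles.csv")
    return [
        RiskProfile(r.arm, r.outcome, r.sex, float(r.mean_risk_pct), float(r.se_pct))
        for r in df.itertuples()
    ]


def fixture_risk_engine() -> list[RiskProfile]:
    """Risk engine returning the packaged published values.

    Drop-in for :func:`capicea.risk_effects.risk_source`; a user-supplied
    engine wrapping an actual risk-equation implementation has the same
    signature.
    """
    return load_risk_profiles()


def load_uncertainty_parameters() -> list[UncertaintyParameter]:
    """The 14 uncertainty parameters of the sensitivity analysis."""
    df = _data("uncertainty.csv")
    return [
        UncertaintyParameter(r.name, float(r.mean), float(r.lower), float(r.upper), r.kind)
        for r in df.itertuples()
    ]


def load_hazard_ratios() -> HazardRatioSet:
    """Central hazard ratios of fatal CHD/stroke in people with diabetes."""
    means = {p.name: p.mean for p in load_uncertainty_parameters()}
    return HazardRatioSet(
        rr_fatal_chd_male=means["hr_fatal_chd_male"],
        rr_fatal_chd_female=means["hr_fatal_chd_female"],
        rr_fatal_stroke_male=means["hr_fatal_stroke_male"],
        rr_fatal_stroke_female=means["hr_fatal_stroke_female"],
    )


def load_published_lifetable() -> pd.DataFrame:
    """Published life-table summary (both sexes, both arms).

    Columns: sex, band_start, band_width (-1 = open-ended), population
    (reported diabetic population in the band), and l / T / e per arm.
    """
    return _data("published_lifetable.csv")
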