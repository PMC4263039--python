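"""Configuration, CSV dialects, report writers and the full-analysis runner.

All tabular formats are UTF-8 comma-separated CSV with a mandatory header
row and period decimal separator.  Age bands are encoded as an integer
``band_start`` plus ``band_width`` with -1 meaning open-ended, avoiding
string parsing of labels like "75+".  The run summary is JSON with a
``schema_version`` field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .cea import UncertaintyParameter, bootstrap_psa, wtp_analysis
from .costing import (
    COMPONENT_NAMES,
    CostComparison,
    CostModel,
    build_cost_model,
    compare_costs,
    round_pct,
)
from .lifetable import AgeBand, LifeTable, MortalitySchedule
from .pipeline import PipelineInputs, evaluate_point, make_pipeline_model
from .risk_effects import (
    RiskProfile,
    cost_consequence,
    reduction_grid,
    risk_source,
)
from .synthetic import SyntheticConfig, gen_mortality_schedule, gen_population

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_run_config",
    "read_cost_components",
    "read_risk_profiles",
    "read_mortality_schedules",
    "write_mortality_schedules",
    "read_population",
    "write_population",
    "read_uncertainty_parameters",
    "write_risk_profiles",
    "cost_table_frame",
    "write_cost_report",
    "risk_report_frame",
    "lifetable_frame",
    "write_psa_samples",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised on malformed run configuration."""


# ---------------------------------------------------------------------------
# CSV readers / writers


def read_cost_components(path) -> dict[str, CostModel]:
    """Read ``arm,component,category,amount_zar`` into per-arm cost models."""
    df = pd.read_csv(path, dtype={"amount_zar": str})
    required = {"arm", "component", "category", "amount_zar"}
    if not required.issubset(df.columns):
        raise ConfigError(f"cost CSV must have columns {sorted(required)}")
    return {
        arm: build_cost_model(arm, {r.component: r.amount_zar for r in grp.itertuples()})
        for arm, grp in df.groupby("arm")
    }


def read_risk_profiles(path) -> list[RiskProfile]:
    """Read ``arm,outcome,sex,mean_risk_pct,se_pct`` into RiskProfiles."""
    df = pd.read_csv(path)
    return [
        RiskProfile(r.arm, r.outcome, r.sex, float(r.mean_risk_pct), float(r.se_pct))
        for r in df.itertuples()
    ]


def write_risk_profiles(profiles, path) -> None:
    pd.DataFrame(
        [
            {
                "arm": p.arm,
                "outcome": p.outcome,
                "sex": p.sex,
                "mean_risk_pct": p.mean_risk,
                "se_pct": p.se,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def _bands_from_rows(starts, widths) -> tuple[AgeBand, ...]:
    return tuple(
        AgeBand(int(s), None if int(w) < 0 else int(w)) for s, w in zip(starts, widths)
    )


def read_mortality_schedules(path) -> dict[str, MortalitySchedule]:
    """Read ``sex,band_start,band_width,m_total,m_ihd,m_stroke`` per sex."""
    df = pd.read_csv(path)
    out = {}
    for sex, grp in df.groupby("sex"):
        grp = grp.sort_values("band_start")
        out[sex] = MortalitySchedule(
            sex=sex,
            bands=_bands_from_rows(grp.band_start, grp.band_width),
            m_total=grp.m_total.to_numpy(float),
            m_ihd=grp.m_ihd.to_numpy(float),
            m_stroke=grp.m_stroke.to_numpy(float),
        )
    return out


def write_mortality_schedules(schedules, path) -> None:
    rows = []
    for sex, s in schedules.items():
        for i, b in enumerate(s.bands):
            rows.append(
                {
                    "sex": sex,
                    "band_start": b.start,
                    "band_width": -1 if b.open else b.width,
                    "m_total": s.m_total[i],
                    "m_ihd": s.m_ihd[i],
                    "m_stroke": s.m_stroke[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_population(path) -> tuple[tuple[AgeBand, ...], np.ndarray]:
    """Read ``band_start,band_width,count`` population counts."""
    df = pd.read_csv(path).sort_values("band_start")
    bands = _bands_from_rows(df.band_start, df.band_width)
    return bands, df["count"].to_numpy(float)


def write_population(bands, counts, path) -> None:
    pd.DataFrame(
        {
            "band_start": [b.start for b in bands],
            "band_width": [-1 if b.open else b.width for b in bands],
            "count": np.asarray(counts),
        }
    ).to_csv(path, index=False)


def read_uncertainty_parameters(path) -> list[UncertaintyParameter]:
    """Read ``name,kind,mean,lower,upper`` uncertainty parameters."""
    df = pd.read_csv(path)
    return [
        UncertaintyParameter(r.name, float(r.mean), float(r.lower), float(r.upper), r.kind)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Report frames


def cost_table_frame(cmp: CostComparison) -> pd.DataFrame:
    """Published-cost-table-shaped frame: one row per component plus totals."""
    rows = []
    for name in COMPONENT_NAMES:
        rows.append(
            {
                "component": name,
                "intervention_zar": float(cmp.intervention.amount(name)),
                "comparator_zar": float(cmp.comparator.amount(name)),
                "difference_zar": float(cmp.diff_per_component[name]),
                "difference_pct": round_pct(cmp.pct_per_component[name]),
            }
        )
    i, c = cmp.intervention, cmp.comparator
    rows.append(
        {
            "component": "total_direct",
            "intervention_zar": float(i.total_direct),
            "comparator_zar": float(c.total_direct),
            "difference_zar": float(i.total_direct - c.total_direct),
            "difference_pct": round_pct(
                100 * (i.total_direct - c.total_direct) / c.total_direct
            ),
        }
    )
    rows.append(
        {
            "component": "total",
            "intervention_zar": float(i.total),
            "comparator_zar": float(c.total),
            "difference_zar": float(cmp.diff_total),
            "difference_pct": round_pct(cmp.pct_total),
        }
    )
    return pd.DataFrame(rows)


def write_cost_report(cmp: CostComparison, csv_path, text_path=None) -> None:
    frame = cost_table_frame(cmp)
    frame.to_csv(csv_path, index=False)
    if text_path is not None:
        Path(text_path).write_text(frame.to_string(index=False) + "\n")


def risk_report_frame(grid, cmp: CostComparison) -> pd.DataFrame:
    """Risk-reduction report: means, SEs, ARR and cost per 1% ARR per cell."""
    reductions = reduction_grid(grid)
    rows = []
    for (outcome, sex), rr in reductions.items():
        intv = grid[("intervention", outcome, sex)]
        comp = grid[("comparator", outcome, sex)]
        cc = cost_consequence(cmp, rr).cost_per_pct_arr if rr.arr > 0 else float("nan")
        rows.append(
            {
                "outcome": outcome,
                "sex": sex,
                "intervention_risk_pct": intv.mean_risk,
                "intervention_se_pct": intv.se,
                "comparator_risk_pct": comp.mean_risk,
                "comparator_se_pct": comp.se,
                "arr_pct_points": rr.arr,
                "rr_m": rr.rr_m,
                "cost_per_pct_arr_zar": cc,
            }
        )
    return pd.DataFrame(rows)


def lifetable_frame(comp_lt: LifeTable, intv_lt: LifeTable, population=None) -> pd.DataFrame:
    """Published-life-table-shaped frame for one sex (both arms side by side)."""
    rows = []
    for i, b in enumerate(comp_lt.bands):
        row = {
            "band_start": b.start,
            "band_width": -1 if b.open else b.width,
            "l_comparator": comp_lt.l_x[i],
            "T_comparator": comp_lt.T_x[i],
            "e_comparator": comp_lt.e_x[i],
            "l_intervention": intv_lt.l_x[i],
            "T_intervention": intv_lt.T_x[i],
            "e_intervention": intv_lt.e_x[i],
        }
        if population is not None:
            row["population"] = float(np.asarray(population)[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_psa_samples(psa, path, scatter_path=None) -> None:
    """Per-iteration PSA output, and optional cost-effectiveness-plane data."""
    frame = pd.DataFrame(
        {
            "iteration": np.arange(len(psa.icer_samples)),
            "incremental_cost": psa.cost_samples,
            "lyg": psa.lyg_samples,
            "icer": psa.icer_samples,
        }
    )
    if psa.draws:
        for name, vals in psa.draws.items():
            frame[f"draw_{name}"] = vals
    frame.to_csv(path, index=False)
    if scatter_path is not None:
        frame[["lyg", "incremental_cost"]].to_csv(scatter_path, index=False)


# ---------------------------------------------------------------------------
# Run configuration

_KNOWN_KEYS = {
    "costs_csv": None,
    "risks_csv": None,
    "mortality_csv": None,
    "population_csv": None,
    "uncertainty_csv": None,
    "seed": 0,
    "iterations": 1000,
    "wtp_threshold": None,
    "currency_rate": 8.21,
    "national_strategy": "per_band_delta_e",
    "output_dir": "capicea_output",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full analysis run.

    File paths left unset fall back to packaged fixtures (costs, risks,
    uncertainty parameters) or to synthetic generation under ``seed``
    (mortality schedules, population); each fallback is logged.
    """

    costs_csv: str | None = None
    risks_csv: str | None = None
    mortality_csv: str | None = None
    population_csv: str | None = None
    uncertainty_csv: str | None = None
    seed: int = 0
    iterations: int = 1000
    wtp_threshold: float | None = None
    currency_rate: float = 8.21
    national_strategy: str = "per_band_delta_e"
    output_dir: str = "capicea_output"
    defaults_applied: tuple[str, ...] = field(default=(), compare=False)


def load_run_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys, non-positive iteration counts and missing referenced
    files raise descriptive errors naming the offending key.  Every
    defaulted optional setting is recorded (and logged) so no default is
    silent.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - set(_KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    merged = dict(_KNOWN_KEYS)
    merged.update(raw)
    defaults = tuple(
        f"{k} = {_KNOWN_KEYS[k]!r} (default)" for k in _KNOWN_KEYS if k not in raw
    )
    if int(merged["iterations"]) < 1:
        raise ConfigError("iterations must be >= 1")
    if merged["wtp_threshold"] is not None and float(merged["wtp_threshold"]) <= 0:
        raise ConfigError("wtp_threshold must be positive")
    for key in ("costs_csv", "risks_csv", "mortality_csv", "population_csv", "uncertainty_csv"):
        if merged[key] is not None and not Path(merged[key]).exists():
            raise ConfigError(f"{key}: file not found: {merged[key]}")
    for line in defaults:
        logger.info("config default: %s", line)
    return RunConfig(
        costs_csv=merged["costs_csv"],
        risks_csv=merged["risks_csv"],
        mortality_csv=merged["mortality_csv"],
        population_csv=merged["population_csv"],
        uncertainty_csv=merged["uncertainty_csv"],
        seed=int(merged["seed"]),
        iterations=int(merged["iterations"]),
        wtp_threshold=None if merged["wtp_threshold"] is None else float(merged["wtp_threshold"]),
        currency_rate=float(merged["currency_rate"]),
        national_strategy=str(merged["national_strategy"]),
        output_dir=str(merged["output_dir"]),
        defaults_applied=defaults,
    )


# ---------------------------------------------------------------------------
# Full analysis


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute costing -> risk effects -> life tables -> CEA and write reports.

    Outputs under ``cfg.output_dir``: cost table CSV + text, risk-reduction
    report CSV, per-sex life-table CSVs, PSA sample and scatter CSVs, and a
    ``summary.json``.  Identical config + seed gives byte-identical output.
    Returns the summary dictionary.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = list(cfg.defaults_applied)

    @_stage("costing")
    def costing_stage():
        if cfg.costs_csv:
            models = read_cost_components(cfg.costs_csv)
        else:
            models = datasets.load_cost_models()
            log.append("costs: packaged fixture table")
        return compare_costs(models["intervention"], models["comparator"])

    @_stage("risk_effects")
    def risk_stage(cmp):
        if cfg.risks_csv:
            profiles = read_risk_profiles(cfg.risks_csv)
        else:
            profiles = datasets.load_risk_profiles()
            log.append("risks: packaged fixture grid")
        grid = risk_source(lambda: profiles)
        return grid, risk_report_frame(grid, cmp)

    @_stage("lifetable")
    def lifetable_inputs():
        if cfg.mortality_csv:
            schedules = read_mortality_schedules(cfg.mortality_csv)
        else:
            scfg = SyntheticConfig(seed=cfg.seed)
            schedules = {s: gen_mortality_schedule(scfg, s) for s in ("male", "female")}
            log.append(f"mortality: synthetic Gompertz schedules (seed {cfg.seed})")
        if cfg.population_csv:
            _, pop = read_population(cfg.population_csv)
        else:
            pop = gen_population(SyntheticConfig(seed=cfg.seed)).astype(float)
            log.append(f"population: synthetic age distribution (seed {cfg.seed})")
        return PipelineInputs(schedules, pop, strategy=cfg.national_strategy)

    @_stage("cea")
    def cea_stage(inputs):
        if cfg.uncertainty_csv:
            params = read_uncertainty_parameters(cfg.uncertainty_csv)
        else:
            params = datasets.load_uncertainty_parameters()
            log.append("uncertainty: packaged fixture parameters")
        point = evaluate_point(inputs, params)
        psa = bootstrap_psa(
            make_pipeline_model(inputs), params, iterations=cfg.iterations, seed=cfg.seed
        )
        return params, point, psa

    cmp = costing_stage()
    grid, risk_frame = risk_stage(cmp)
    inputs = lifetable_inputs()
    params, point, psa = cea_stage(inputs)

    write_cost_report(cmp, out / "cost_table.csv", out / "cost_table.txt")
    risk_frame.to_csv(out / "risk_reductions.csv", index=False)
    for sex, (comp_lt, intv_lt) in point.tables.items():
        lifetable_frame(comp_lt, intv_lt, inputs.sex_population(sex)).to_csv(
            out / f"lifetable_{sex}.csv", index=False
        )
    write_psa_samples(psa, out / "psa_samples.csv", out / "ce_plane.csv")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "iterations": cfg.iterations,
        "diff_total": float(cmp.diff_total),
        "pct_total": round_pct(cmp.pct_total),
        "national_strategy": cfg.national_strategy,
        "point_icer": point.icer,
        "national_cost": point.national_cost,
        "national_lyg": point.national_lyg,
        "lyg_per_capita": point.lyg_per_capita,
        "psa_mean_icer": psa.mean_icer,
        "psa_ci": [psa.ci_low, psa.ci_high],
        "psa_mean_lyg": psa.mean_lyg,
        "psa_excluded": psa.n_excluded,
        "run_log": log,
    }
    if cfg.wtp_threshold is not None:
        wtp = wtp_analysis(psa, cfg.wtp_threshold)
        summary["wtp_threshold"] = wtp.threshold
        summary["wtp_fraction_below"] = wtp.fraction_below
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    for line in log:
        logger.info("run: %s", line)
    return summary
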