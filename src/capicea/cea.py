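"""ICERs, bootstrap probabilistic sensitivity analysis and WTP analysis.

The incremental cost-effectiveness ratio is the conventional

    ICER = (I_cost - C_cost) / (I_effect - C_effect)

with effects measured in life-years gained (LYG).  Parameter uncertainty is
propagated by a bootstrap: each uncertainty parameter (hazard ratios of
fatal CHD/stroke in diabetics, 10-year fatal-event risks per arm, per-capita
costs per arm) gets a sampling distribution fitted to its reported mean and
2.5/97.5 percentile bounds; on every iteration a joint draw is pushed
through the whole pipeline (risks -> mortality ratios -> life tables ->
LYG -> ICER) and the resulting ICER distribution summarised by its mean and
percentile confidence interval.  Willingness-to-pay analysis reports the
fraction of iterations falling below a cost-per-LYG threshold (the WHO
"highly cost-effective" criterion uses national GDP per capita).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .costing import CostComparison

__all__ = [
    "EffectPair",
    "UncertaintyParameter",
    "ParameterSampler",
    "PSAResult",
    "WTPResult",
    "CEAError",
    "icer",
    "fit_distribution",
    "bootstrap_psa",
    "wtp_analysis",
    "national_projection",
    "NATIONAL_STRATEGIES",
]

logger = logging.getLogger(__name__)

#: Resampling floor for positivity-constrained draws.
TRUNCATION_EPS = 1e-6

PARAM_KINDS = ("hazard_ratio", "risk_pct", "cost_zar")


class CEAError(ValueError):
    """Raised on undefined ICERs, invalid parameters or empty samples."""


@dataclass(frozen=True)
class EffectPair:
    """Life-year effects of the two arms (intervention, comparator)."""

    i_effect: float
    c_effect: float

    def __post_init__(self):
        if not (np.isfinite(self.i_effect) and np.isfinite(self.c_effect)):
            raise CEAError("effects must be finite")


def icer(i_cost: float, c_cost: float, effects: EffectPair) -> float:
    """Incremental cost per unit incremental effect."""
    d_effect = effects.i_effect - effects.c_effect
    if d_effect == 0:
        raise CEAError("zero incremental effect; ICER undefined (consider dominance)")
    return (float(i_cost) - float(c_cost)) / d_effect


@dataclass(frozen=True)
class UncertaintyParameter:
    """One uncertain model input with mean and 2.5/97.5 percentile bounds."""

    name: str
    mean: float
    lower: float
    upper: float
    kind: str = "hazard_ratio"

    def __post_init__(self):
        if self.kind not in PARAM_KINDS:
            raise CEAError(f"unknown parameter kind {self.kind!r}")
        if self.upper < self.lower:
            raise CEAError(f"{self.name}: upper bound below lower bound")
        if not self.lower <= self.mean <= self.upper:
            raise CEAError(f"{self.name}: mean outside [lower, upper]")

    @property
    def sd(self) -> float:
        """Normal SD implied by the bounds: (upper - lower) / (2 * 1.96)."""
        return (self.upper - self.lower) / (2.0 * 1.959963984540054)


@dataclass
class ParameterSampler:
    """Normal sampler fitted to a parameter, truncated below at a floor.

    The reported bounds are read as 2.5/97.5 percentiles of a normal.  All
    three parameter kinds are physically positive, so draws at or below the
    floor are rejected and redrawn (the rejection count is tracked).  A
    zero-width parameter degenerates to its mean.
    """

    parameter: UncertaintyParameter
    n_resampled: int = field(default=0, init=False)

    def draw(self, rng: np.random.Generator, size: int | None = None) -> float | np.ndarray:
        p = self.parameter
        if p.sd == 0:
            return p.mean if size is None else np.full(size, p.mean)
        n = 1 if size is None else size
        out = rng.normal(p.mean, p.sd, size=n)
        bad = out <= TRUNCATION_EPS
        while np.any(bad):
            self.n_resampled += int(bad.sum())
            out[bad] = rng.normal(p.mean, p.sd, size=int(bad.sum()))
            bad = out <= TRUNCATION_EPS
        return float(out[0]) if size is None else out


def fit_distribution(p: UncertaintyParameter) -> ParameterSampler:
    """Sampler for one uncertainty parameter (see ParameterSampler)."""
    return ParameterSampler(p)


@dataclass(frozen=True)
class PSAResult:
    """Bootstrap ICER distribution with percentile confidence interval."""

    iterations: int
    icer_samples: np.ndarray
    lyg_samples: np.ndarray
    cost_samples: np.ndarray  # incremental cost per draw
    mean_icer: float
    ci_low: float
    ci_high: float
    mean_lyg: float
    lyg_ci: tuple[float, float]
    seed: int
    n_excluded: int = 0
    draws: dict[str, np.ndarray] | None = None


# A pipeline closure maps one joint parameter draw (name -> value) to
# (incremental cost, LYG, ICER).
PipelineModel = Callable[[Mapping[str, float]], tuple[float, float, float]]


def bootstrap_psa(
    model: PipelineModel,
    params: Sequence[UncertaintyParameter],
    iterations: int = 1000,
    seed: int = 0,
    keep_draws: bool = False,
) -> PSAResult:
    """Propagate parameter uncertainty through the full pipeline.

    Draws are jointly independent (no correlation structure is available
    for these parameters).  Draws producing zero LYG leave the ICER
    undefined; they are excluded with a logged count, and more than 10%
    exclusions aborts the analysis.  Fully reproducible for a fixed seed.
    """
    if iterations < 1:
        raise CEAError("iterations must be >= 1")
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise CEAError("duplicate parameter names")
    rng = np.random.default_rng(seed)
    samplers = {p.name: fit_distribution(p) for p in params}

    draw_log: dict[str, list[float]] = {n: [] for n in names}
    icers, lygs, costs = [], [], []
    n_excluded = 0
    for _ in range(iterations):
        draw = {name: samplers[name].draw(rng) for name in names}
        d_cost, lyg, icer_val = model(draw)
        if lyg == 0:
            n_excluded += 1
            continue
        icers.append(icer_val)
        lygs.append(lyg)
        costs.append(d_cost)
        if keep_draws:
            for n in names:
                draw_log[n].append(draw[n])
    if n_excluded:
        logger.warning("excluded %d of %d draws with zero LYG", n_excluded, iterations)
    if n_excluded > 0.10 * iterations:
        raise CEAError(
            f"{n_excluded}/{iterations} draws produced zero LYG; model mis-specified"
        )
    icer_arr = np.asarray(icers)
    lyg_arr = np.asarray(lygs)
    ci = np.percentile(icer_arr, [2.5, 97.5])
    lyg_ci = np.percentile(lyg_arr, [2.5, 97.5])
    return PSAResult(
        iterations=iterations,
        icer_samples=icer_arr,
        lyg_samples=lyg_arr,
        cost_samples=np.asarray(costs),
        mean_icer=float(icer_arr.mean()),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        mean_lyg=float(lyg_arr.mean()),
        lyg_ci=(float(lyg_ci[0]), float(lyg_ci[1])),
        seed=seed,
        n_excluded=n_excluded,
        draws={n: np.asarray(v) for n, v in draw_log.items()} if keep_draws else None,
    )


@dataclass(frozen=True)
class WTPResult:
    """Fraction of bootstrap ICERs below a willingness-to-pay threshold."""

    threshold: float  # ZAR per LYG
    fraction_below: float
    n_samples: int


def wtp_analysis(psa: PSAResult, threshold: float) -> WTPResult:
    """Fraction of ICER samples strictly below the threshold."""
    if threshold <= 0:
        raise CEAError("WTP threshold must be positive")
    if psa.icer_samples.size == 0:
        raise CEAError("no ICER samples")
    frac = float(np.mean(psa.icer_samples < threshold))
    return WTPResult(threshold=threshold, fraction_below=frac, n_samples=psa.icer_samples.size)


NATIONAL_STRATEGIES = ("per_band_delta_e", "cohort_scaling")


def national_projection(
    per_capita_costs: CostComparison,
    population_by_band: Sequence[float],
    strategy: str = "per_band_delta_e",
    delta_e_by_band: Sequence[float] | None = None,
    per_capita_lyg: float | None = None,
) -> tuple[float, float]:
    """Scale per-capita cost and life-year results to the national level.

    National incremental cost is the per-capita cost difference times the
    total diabetic population.  National LYG depends on the strategy:

    * ``per_band_delta_e`` (default): sum over bands of the band population
      times the life-expectancy gain of that band, crediting each current
      cohort its remaining-lifetime gain (requires ``delta_e_by_band``);
    * ``cohort_scaling``: per-capita LYG of the age-25 cohort times the
      total population (requires ``per_capita_lyg``).
    """
    pop = np.asarray(population_by_band, dtype=float)
    if np.any(pop < 0):
        raise CEAError("populations must be non-negative")
    total_pop = float(pop.sum())
    national_cost = float(per_capita_costs.diff_total) * total_pop
    if strategy == "per_band_delta_e":
        if delta_e_by_band is None:
            raise CEAError("per_band_delta_e strategy requires delta_e_by_band")
        de = np.asarray(delta_e_by_band, dtype=float)
        if de.shape != pop.shape:
            raise CEAError("delta_e_by_band and population_by_band lengths differ")
        national_lyg = float((pop * de).sum())
    elif strategy == "cohort_scaling":
        if per_capita_lyg is None:
            raise CEAError("cohort_scaling strategy requires per_capita_lyg")
        national_lyg = float(per_capita_lyg) * total_pop
    else:
        raise CEAError(f"unknown national strategy {strategy!r}")
    return national_cost, national_lyg
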