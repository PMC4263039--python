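"""Abridged multi-state life tables with cause-decomposed mortality.

The evaluation compares two stationary populations of people with type-2
diabetes: one experiencing current diabetic mortality (comparator) and one
whose cardiovascular mortality is scaled down by the intervention's
mortality reduction ratio.  Mortality enters as age-band x sex schedules of
all-cause (M_T), ischaemic heart disease and stroke rates per person-year;
CVD mortality (M_CVD = m_ihd + m_stroke) is separated from other-cause
mortality (M_other = M_T - M_CVD), inflated to the diabetic population by
cause- and sex-specific hazard ratios, and only the CVD part responds to
the intervention.

Tables are abridged: bands are 10-year by default from age 25 with an open
final band.  Within a closed band of width n the rate M converts to a death
probability via q = n*M / (1 + n*(1-a)*M) with a = 0.5 (deaths on average
half-way through the band); the open band contributes L = l/M person-years
(stationary-population convention).  Remaining life expectancy is
e_x = T_x / l_x with T_x the person-years lived after the band start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AgeBand",
    "default_bands",
    "MortalitySchedule",
    "DecomposedMortality",
    "HazardRatioSet",
    "LifeTable",
    "LifeTableError",
    "decompose_mortality",
    "diabetic_cvd_mortality",
    "apply_intervention",
    "build_life_table",
    "life_years_gained",
    "band_to_q",
]


class LifeTableError(ValueError):
    """Raised on invalid mortality schedules or mismatched tables."""


@dataclass(frozen=True)
class AgeBand:
    """One age band: [start, start+width), or open-ended if width is None."""

    start: int
    width: int | None = 10  # None = open-ended ("75+")

    @property
    def open(self) -> bool:
        return self.width is None

    @property
    def midpoint(self) -> float:
        # An open band has no true midpoint; use the nominal-width centre,
        # which is where a representative rate is evaluated.
        w = 10 if self.open else self.width
        return self.start + w / 2.0

    @property
    def label(self) -> str:
        return f"{self.start}+" if self.open else f"{self.start}-{self.start + self.width - 1}"


def default_bands(start: int = 25, width: int = 10, n_closed: int = 5) -> tuple[AgeBand, ...]:
    """Standard band layout: n_closed closed bands then an open band.

    Defaults give 25-34 ... 65-74, 75+.  Analysis starts at 25 because
    including younger ages substantially over-states years of life gained.
    """
    bands = [AgeBand(start + i * width, width) for i in range(n_closed)]
    bands.append(AgeBand(start + n_closed * width, None))
    return tuple(bands)


def _check_bands(bands: Sequence[AgeBand]) -> None:
    if not bands:
        raise LifeTableError("at least one age band required")
    for a, b in zip(bands, bands[1:]):
        if a.open:
            raise LifeTableError("only the last band may be open-ended")
        if b.start != a.start + a.width:
            raise LifeTableError(f"bands not contiguous at {a.label} -> {b.label}")
    if not bands[-1].open:
        raise LifeTableError("last band must be open-ended")


@dataclass(frozen=True)
class MortalitySchedule:
    """All-cause, IHD and stroke mortality rates per person-year, by band."""

    sex: str
    bands: tuple[AgeBand, ...]
    m_total: np.ndarray
    m_ihd: np.ndarray
    m_stroke: np.ndarray

    def __post_init__(self):
        _check_bands(self.bands)
        for name in ("m_total", "m_ihd", "m_stroke"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.bands),):
                raise LifeTableError(f"{name} must have one rate per band")
            if np.any(arr < 0):
                raise LifeTableError(f"{name} contains negative rates")
            object.__setattr__(self, name, arr)
        if np.any(self.m_total <= 0):
            raise LifeTableError("all-cause rates must be positive")
        if np.any(self.m_ihd + self.m_stroke > self.m_total * (1 + 1e-12)):
            raise LifeTableError("cause-specific rates exceed all-cause rate")


@dataclass(frozen=True)
class DecomposedMortality:
    """Mortality split into CVD (IHD + stroke) and other causes, by band.

    Retains the cause-specific components so hazard ratios and intervention
    reductions can be applied per cause.  Invariant: m_cvd + m_other equals
    the recomposed total exactly.
    """

    sex: str
    bands: tuple[AgeBand, ...]
    m_ihd: np.ndarray
    m_stroke: np.ndarray
    m_other: np.ndarray

    @property
    def m_cvd(self) -> np.ndarray:
        return self.m_ihd + self.m_stroke

    @property
    def m_total(self) -> np.ndarray:
        return self.m_cvd + self.m_other


def decompose_mortality(s: MortalitySchedule) -> DecomposedMortality:
    """Separate CVD mortality from all other causes, per band."""
    m_cvd = s.m_ihd + s.m_stroke
    if np.any(m_cvd > s.m_total * (1 + 1e-12)):
        raise LifeTableError("IHD + stroke exceeds all-cause mortality")
    return DecomposedMortality(
        sex=s.sex,
        bands=s.bands,
        m_ihd=s.m_ihd.copy(),
        m_stroke=s.m_stroke.copy(),
        m_other=s.m_total - m_cvd,
    )


@dataclass(frozen=True)
class HazardRatioSet:
    """Relative risks of fatal CHD / stroke mortality in people with diabetes.

    Sex- and cause-specific, from longitudinal cohort meta-analysis; each
    central value carries lower/upper uncertainty bounds used by the PSA.
    """

    rr_fatal_chd_male: float
    rr_fatal_chd_female: float
    rr_fatal_stroke_male: float
    rr_fatal_stroke_female: float

    def __post_init__(self):
        for f in (
            "rr_fatal_chd_male",
            "rr_fatal_chd_female",
            "rr_fatal_stroke_male",
            "rr_fatal_stroke_female",
        ):
            if getattr(self, f) <= 0:
                raise LifeTableError(f"{f} must be positive")

    def for_sex(self, sex: str) -> tuple[float, float]:
        """(CHD hazard ratio, stroke hazard ratio) for one sex."""
        if sex == "male":
            return self.rr_fatal_chd_male, self.rr_fatal_stroke_male
        if sex == "female":
            return self.rr_fatal_chd_female, self.rr_fatal_stroke_female
        raise LifeTableError(f"unknown sex {sex!r}")


def diabetic_cvd_mortality(
    d: DecomposedMortality, hr: HazardRatioSet, sex: str | None = None
) -> DecomposedMortality:
    """Inflate CVD mortality to the diabetic population.

    IHD and stroke rates are each multiplied by the sex-appropriate hazard
    ratio (cause-specifically, then summed into diabetic CVD mortality);
    other-cause mortality is left unchanged.
    """
    rr_chd, rr_stroke = hr.for_sex(sex or d.sex)
    return replace(d, m_ihd=d.m_ihd * rr_chd, m_stroke=d.m_stroke * rr_stroke)


def apply_intervention(
    d: DecomposedMortality, rr_m: float, rr_m_stroke: float | None = None
) -> DecomposedMortality:
    """Scale CVD mortality by the intervention's mortality reduction ratio.

    With one argument, ``rr_m`` is a pooled CVD ratio applied to both
    causes; with ``rr_m_stroke`` given, ``rr_m`` applies to IHD and
    ``rr_m_stroke`` to stroke (cause-specific mode).  Other-cause mortality
    is untouched and the total recomposes as the sum.
    """
    rr_s = rr_m if rr_m_stroke is None else rr_m_stroke
    if rr_m <= 0 or rr_s <= 0:
        raise LifeTableError("mortality reduction ratios must be positive")
    return replace(d, m_ihd=d.m_ihd * rr_m, m_stroke=d.m_stroke * rr_s)


def band_to_q(m: float, width: float, a: float = 0.5) -> float:
    """Death probability over a closed band from its central rate.

    q = n*M / (1 + n*(1-a)*M), with a the average fraction of the band
    lived by those dying in it.  a = 0.5 is the standard half-interval
    assumption; the conversion is isolated here so an alternative (e.g.
    constant hazard within band, q = 1 - exp(-n*M)) can be swapped in.
    """
    return width * m / (1.0 + width * (1.0 - a) * m)


@dataclass(frozen=True)
class LifeTable:
    """Abridged life table: survivors, person-years, life expectancy by band."""

    sex: str
    bands: tuple[AgeBand, ...]
    radix: float
    l_x: np.ndarray  # survivors at band start
    L_band: np.ndarray  # person-years lived within the band
    T_x: np.ndarray  # cumulative person-years lived after band start
    e_x: np.ndarray  # remaining life expectancy at band start

    @property
    def band_starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bands])


def build_life_table(
    mortality: np.ndarray | Sequence[float],
    radix: float,
    bands: Sequence[AgeBand] | None = None,
    sex: str = "",
    a: float = 0.5,
) -> LifeTable:
    """Build an abridged life table from per-band total mortality rates.

    ``mortality`` holds one rate per band (per person-year).  Closed bands
    use the q conversion of :func:`band_to_q`; the open band contributes
    L = l/M person-years and absorbs all remaining survivors.
    """
    m = np.asarray(mortality, dtype=float)
    bands = tuple(bands) if bands is not None else default_bands()
    _check_bands(bands)
    if m.shape != (len(bands),):
        raise LifeTableError("one mortality rate per band required")
    if radix <= 0:
        raise LifeTableError("radix must be positive")
    if np.any(m < 0):
        raise LifeTableError("mortality rates must be non-negative")
    if m[-1] <= 0:
        raise LifeTableError("open-band rate must be positive (L = l/M)")

    n_bands = len(bands)
    l_x = np.empty(n_bands)
    L = np.empty(n_bands)
    l = float(radix)
    for i, band in enumerate(bands):
        l_x[i] = l
        if band.open:
            L[i] = l / m[i]
        else:
            n = float(band.width)
            q = band_to_q(m[i], n, a)
            deaths = l * q
            L[i] = n * (l - deaths) + a * n * deaths
            l -= deaths
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l_x > 0, T / l_x, 0.0)
    return LifeTable(sex=sex, bands=bands, radix=float(radix), l_x=l_x, L_band=L, T_x=T, e_x=e)


def life_years_gained(
    intervention_lt: LifeTable, comparator_lt: LifeTable
) -> tuple[float, np.ndarray]:
    """Cohort life-years gained and per-band life-expectancy differences.

    Returns (T_start(intervention) - T_start(comparator), e_x differences).
    Both tables must share radix and band layout.
    """
    if intervention_lt.bands != comparator_lt.bands:
        raise LifeTableError("life tables have different band layouts")
    if intervention_lt.radix != comparator_lt.radix:
        raise LifeTableError("life tables have different radices")
    lyg = float(intervention_lt.T_x[0] - comparator_lt.T_x[0])
    return lyg, intervention_lt.e_x - comparator_lt.e_x
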