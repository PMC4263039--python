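"""Per-capita annual cost models for the two arms of the programme.

The intervention is a capitated diabetes management programme adapted to
primary health care; the comparator is tertiary-level usual practice.
Each arm is costed as five canonical annual per-capita components:
four direct (compensation, training, investigations, medication and
consumables) and one indirect (overheads).

Amounts are South African rand (ZAR) and are held as exact decimal cents:
the published accounting is exact to the cent and must reproduce without
floating-point drift.  USD figures are display-only conversions at a
configurable average exchange rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

__all__ = [
    "COMPONENT_NAMES",
    "DIRECT_COMPONENTS",
    "INDIRECT_COMPONENTS",
    "CostComponent",
    "CostModel",
    "CostComparison",
    "CostingError",
    "build_cost_model",
    "apply_incentive_bonus",
    "compare_costs",
    "consumables_cost",
    "round_pct",
]

#: Canonical component names, in report order.
DIRECT_COMPONENTS = (
    "compensation",
    "training",
    "investigations",
    "medication_consumables",
)
INDIRECT_COMPONENTS = ("overheads",)
COMPONENT_NAMES = DIRECT_COMPONENTS + INDIRECT_COMPONENTS

CENT = Decimal("0.01")


class CostingError(ValueError):
    """Raised on invalid cost inputs (negative amounts, duplicates, ...)."""


def _as_money(value) -> Decimal:
    """Coerce to a Decimal quantized to cents.

    Floats are routed through ``str`` so that 0.1 becomes Decimal('0.10'),
    not the binary artefact.
    """
    if isinstance(value, Decimal):
        d = value
    else:
        d = Decimal(str(value))
    return d.quantize(CENT)


@dataclass(frozen=True)
class CostComponent:
    """One annual per-capita cost line.

    ``category`` is ``direct`` for compensation, training, investigations
    and medication/consumables, and ``indirect`` for overheads only.
    """

    name: str
    amount: Decimal
    category: str = field(default="")

    def __post_init__(self):
        if self.name not in COMPONENT_NAMES:
            raise CostingError(
                f"unknown cost component {self.name!r}; expected one of {COMPONENT_NAMES}"
            )
        amount = _as_money(self.amount)
        if amount < 0:
            raise CostingError(f"component {self.name!r} has negative amount {amount}")
        expected = "indirect" if self.name in INDIRECT_COMPONENTS else "direct"
        category = self.category or expected
        if category != expected:
            raise CostingError(
                f"component {self.name!r} must be {expected!r}, got {category!r}"
            )
        object.__setattr__(self, "amount", amount)
        object.__setattr__(self, "category", category)


@dataclass(frozen=True)
class CostModel:
    """A validated per-capita annual cost model for one arm.

    Invariant: ``total == total_direct + total_indirect`` exactly, at cent
    precision, with ``total_direct`` the sum of the four direct components
    (plus any incentive bonus applied in scenario analysis).
    """

    arm: str
    components: tuple[CostComponent, ...]
    total_direct: Decimal
    total_indirect: Decimal
    total: Decimal
    currency_rate: Decimal = Decimal("8.21")  # ZAR per USD, display only
    incentive_bonus: Decimal = Decimal("0.00")
    incentive_applied: bool = False

    def component(self, name: str) -> CostComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def amount(self, name: str) -> Decimal:
        return self.component(name).amount

    @property
    def total_usd(self) -> Decimal:
        return (self.total / self.currency_rate).quantize(CENT, rounding=ROUND_HALF_UP)

    def as_dict(self) -> dict[str, float]:
        d = {c.name: float(c.amount) for c in self.components}
        d["total_direct"] = float(self.total_direct)
        d["total_indirect"] = float(self.total_indirect)
        d["total"] = float(self.total)
        return d


def build_cost_model(
    arm: str,
    components: Iterable[CostComponent] | Mapping[str, object],
    currency_rate=Decimal("8.21"),
) -> CostModel:
    """Assemble and validate a cost model from its five components.

    All five canonical names must be present exactly once (training may be
    zero, as it is for the comparator).  ``components`` may be a mapping
    ``name -> amount`` for convenience.
    """
    if arm not in ("intervention", "comparator"):
        raise CostingError(f"arm must be intervention|comparator, got {arm!r}")
    if isinstance(components, Mapping):
        comps = [CostComponent(name, _as_money(a)) for name, a in components.items()]
    else:
        comps = list(components)
    names = [c.name for c in comps]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise CostingError(f"duplicate cost component(s): {sorted(dupes)}")
    missing = set(COMPONENT_NAMES) - set(names)
    if missing:
        raise CostingError(f"missing cost component(s): {sorted(missing)}")
    comps = tuple(sorted(comps, key=lambda c: COMPONENT_NAMES.index(c.name)))
    total_direct = sum((c.amount for c in comps if c.category == "direct"), Decimal(0))
    total_indirect = sum((c.amount for c in comps if c.category == "indirect"), Decimal(0))
    return CostModel(
        arm=arm,
        components=comps,
        total_direct=total_direct,
        total_indirect=total_indirect,
        total=total_direct + total_indirect,
        currency_rate=_as_money(currency_rate).quantize(Decimal("0.0001")),
    )


def apply_incentive_bonus(model: CostModel, training_cost_per_patient) -> CostModel:
    """Add the per-patient incentive bonus to an intervention cost model.

    The programme pays providers a bonus, equal to the training cost per
    patient seen, for every patient managed without a diabetes-related
    emergency.  The published intervention figures already embed this bonus,
    so this operation exists for scenario analysis on models built from raw
    component costs; a flag guards against double application.
    """
    if model.arm != "intervention":
        raise CostingError("incentive bonus applies to the intervention arm only")
    bonus = _as_money(training_cost_per_patient)
    if bonus < 0:
        raise CostingError("incentive bonus must be non-negative")
    if bonus == 0:
        return model
    if model.incentive_applied:
        raise CostingError("incentive bonus already applied to this model")
    return replace(
        model,
        incentive_bonus=bonus,
        incentive_applied=True,
        total_direct=model.total_direct + bonus,
        total=model.total + bonus,
    )


@dataclass(frozen=True)
class CostComparison:
    """Component-wise and total differences between the two arms.

    ``diff_per_component[name]`` is intervention minus comparator;
    ``pct_per_component[name]`` is the difference as a percentage of the
    comparator amount, or None where the comparator amount is zero (the
    published table prints N/A for training).  Percentages are exact
    Decimals here; rounding to one decimal place happens at report time.
    """

    intervention: CostModel
    comparator: CostModel
    diff_per_component: dict[str, Decimal]
    pct_per_component: dict[str, Decimal | None]
    diff_total: Decimal
    pct_total: Decimal

    @property
    def diff_total_usd(self) -> Decimal:
        return (self.diff_total / self.intervention.currency_rate).quantize(
            CENT, rounding=ROUND_HALF_UP
        )


def compare_costs(i: CostModel, c: CostModel) -> CostComparison:
    """Compare two cost models component-wise and in total."""
    if i.currency_rate != c.currency_rate:
        raise CostingError("cost models use different currency rates")
    if c.total == 0:
        raise CostingError("comparator total is zero; percentage difference undefined")
    diffs: dict[str, Decimal] = {}
    pcts: dict[str, Decimal | None] = {}
    for name in COMPONENT_NAMES:
        di = i.amount(name) - c.amount(name)
        diffs[name] = di
        base = c.amount(name)
        pcts[name] = None if base == 0 else Decimal(100) * di / base
    diff_total = i.total - c.total
    return CostComparison(
        intervention=i,
        comparator=c,
        diff_per_component=diffs,
        pct_per_component=pcts,
        diff_total=diff_total,
        pct_total=Decimal(100) * diff_total / c.total,
    )


def consumables_cost(monthly_units, unit_price, months=12) -> Decimal:
    """Annualised consumables cost: units/month x price/unit x months.

    The consumables convention assumes a fixed monthly usage of component
    units (glucose strips, lancets, syringes) per patient.
    """
    if monthly_units < 0 or months < 0:
        raise CostingError("consumables inputs must be non-negative")
    price = _as_money(unit_price)
    if price < 0:
        raise CostingError("unit price must be non-negative")
    return (Decimal(monthly_units) * price * Decimal(months)).quantize(CENT)


def round_pct(value: Decimal | None, places: int = 1) -> float | None:
    """Round a percentage half-up for reporting (one decimal by default)."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-places)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))
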