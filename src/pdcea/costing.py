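"""Resource-based costing of device-aided therapies.

Costs follow the Spanish National Health System (SNS) perspective:
pathway costs aggregate pre-treatment work-up, procedure and follow-up
resource use over a 5-year horizon at public unit costs (EUR 2023);
drug acquisition is priced at ex-factory price (PVL) for standard daily
doses.  Discounting uses the same 3.5% annual rate as the effects.

Timing conventions (configurable): pre-treatment and procedure costs
fall at t = 0 undiscounted; follow-up costs are spread uniformly over
the horizon; annual drug costs recur as an annuity-due (start of year)
because treatment begins immediately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "UnitCost",
    "ResourceUse",
    "DrugRegimen",
    "CostBreakdown",
    "CostingError",
    "parse_money",
    "format_money",
    "pathway_cost",
    "annual_drug_cost",
    "discount_factor_sum",
    "total_cost",
    "therapy_cost_breakdown",
    "read_table",
]

PHASES = ("pretreatment", "procedure", "followup")


class CostingError(ValueError):
    """Raised for unresolvable items or malformed monetary input."""


@dataclass(frozen=True)
class UnitCost:
    item_id: str
    label: str
    unit_cost: float
    source_year: int = 2023
    phase: str = "pretreatment"

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise CostingError(f"unit cost for {self.item_id!r} is negative")
        if self.phase not in PHASES:
            raise CostingError(
                f"unit cost {self.item_id!r}: phase must be one of {PHASES}"
            )


@dataclass(frozen=True)
class ResourceUse:
    therapy_id: str
    item_id: str
    count: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise CostingError(
                f"resource count for {self.item_id!r} is negative"
            )


@dataclass(frozen=True)
class DrugRegimen:
    """Standard daily regimen priced at ex-factory (PVL) level."""

    therapy_id: str
    national_code: str
    pack_price: float
    dose_per_standard_unit: float  # mg of active substance per standard unit
    cost_per_standard_unit: float  # EUR
    standard_units_per_day: float
    daily_dose_mg: float = float("nan")  # informational

    def __post_init__(self) -> None:
        if self.cost_per_standard_unit < 0:
            raise CostingError(
                f"regimen {self.therapy_id!r}: negative cost per unit"
            )
        if self.standard_units_per_day <= 0:
            raise CostingError(
                f"regimen {self.therapy_id!r}: standard_units_per_day must be > 0"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted therapy cost over the horizon, with components."""

    therapy_id: str
    pathway_cost_5y: float  # undiscounted pathway total over the horizon
    drug_cost_annual: float  # undiscounted annual drug cost
    total_cost: float  # discounted total over the horizon
    average_annual_cost: float
    discount_rate: float
    horizon_years: int
    pathway_component: float = 0.0  # discounted
    drug_component: float = 0.0  # discounted


def _decimal(text: str, locale: str) -> Decimal:
    t = text.strip().replace("€", "").replace(" ", "")
    if not t:
        raise CostingError("empty monetary string")
    if locale == "es_ES":
        thousands, decimal = ".", ","
    elif locale == "en_US":
        thousands, decimal = ",", "."
    else:
        raise CostingError(f"unknown locale {locale!r}")
    # integer part either ungrouped or grouped in threes; one decimal part
    pattern = (
        rf"^[+-]?(\d+|\d{{1,3}}(\{thousands}\d{{3}})+)(\{decimal}\d+)?$"
    )
    if not re.match(pattern, t):
        raise CostingError(f"malformed numeral {text!r} for locale {locale}")
    t = t.replace(thousands, "").replace(decimal, ".")
    try:
        return Decimal(t)
    except InvalidOperation:  # pragma: no cover - regex already screens
        raise CostingError(f"malformed numeral {text!r} for locale {locale}") from None


def parse_money(text: str, locale: str = "es_ES") -> float:
    """Parse a monetary string under a decimal-separator convention.

    es_ES uses "." for thousands and "," for decimals ("86.423,86");
    en_US is the reverse.
    """
    return float(_decimal(text, locale))


def format_money(value: float, locale: str = "es_ES", decimals: int = 2) -> str:
    """Format a euro amount to ``decimals`` places in the given locale."""
    q = Decimal(str(value)).quantize(Decimal(1).scaleb(-decimals), ROUND_HALF_UP)
    s = f"{q:,.{decimals}f}"
    if locale == "es_ES":
        s = s.replace(",", "\x00").replace(".", ",").replace("\x00", ".")
    elif locale != "en_US":
        raise CostingError(f"unknown locale {locale!r}")
    return s


def _round_cents(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), ROUND_HALF_UP))


def pathway_cost(
    uses: Iterable[ResourceUse],
    costs: Iterable[UnitCost] | Mapping[str, UnitCost],
) -> float:
    """Total pathway cost: sum of count x unit cost, rounded to cents.

    Every item in ``uses`` must resolve to exactly one :class:`UnitCost`.
    """
    lookup = _cost_lookup(costs)
    total = Decimal(0)
    for use in uses:
        if use.item_id not in lookup:
            raise CostingError(f"no unit cost for item {use.item_id!r}")
        total += Decimal(str(use.count)) * Decimal(str(lookup[use.item_id].unit_cost))
    return _round_cents(total)


def _cost_lookup(costs) -> dict[str, UnitCost]:
    if isinstance(costs, Mapping):
        return dict(costs)
    lookup: dict[str, UnitCost] = {}
    for c in costs:
        if c.item_id in lookup:
            raise CostingError(f"duplicate unit cost for item {c.item_id!r}")
        lookup[c.item_id] = c
    return lookup


def annual_drug_cost(regimen: DrugRegimen, days_per_year: int = 365) -> float:
    """Annual drug acquisition cost, rounded to whole euros.

    cost per standard unit x standard units per day x days per year.
    """
    total = (
        Decimal(str(regimen.cost_per_standard_unit))
        * Decimal(str(regimen.standard_units_per_day))
        * days_per_year
    )
    return float(total.quantize(Decimal("1"), ROUND_HALF_UP))


def discount_factor_sum(horizon_years: int, rate: float, timing: str) -> float:
    """Sum of annual discount factors over the horizon.

    ``start_of_year`` (annuity-due): t = 0..H-1; ``end_of_year``
    (ordinary annuity): t = 1..H.
    """
    if timing == "start_of_year":
        ts = range(horizon_years)
    elif timing == "end_of_year":
        ts = range(1, horizon_years + 1)
    else:
        raise ValueError(f"unknown timing {timing!r}")
    return sum((1.0 + rate) ** (-t) for t in ts)


def total_cost(
    pathway_5y: float,
    drug_annual: float,
    horizon_years: int = 5,
    rate: float = 0.035,
    timing: str = "start_of_year",
    pathway_followup: float = 0.0,
    therapy_id: str = "",
) -> CostBreakdown:
    """Discounted total therapy cost over the horizon.

    ``pathway_5y`` is the full undiscounted pathway cost; the
    ``pathway_followup`` share of it is spread uniformly over the horizon
    and discounted with the drug timing, the remainder falls at t = 0
    undiscounted.  The annual drug cost recurs every year.
    """
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0 <= pathway_followup <= pathway_5y + 1e-9:
        raise ValueError("pathway_followup must be within [0, pathway_5y]")
    ann = discount_factor_sum(horizon_years, rate, timing)
    upfront = pathway_5y - pathway_followup
    pathway_component = upfront + (pathway_followup / horizon_years) * ann
    drug_component = drug_annual * ann
    total = pathway_component + drug_component
    return CostBreakdown(
        therapy_id=therapy_id,
        pathway_cost_5y=pathway_5y,
        drug_cost_annual=drug_annual,
        total_cost=total,
        average_annual_cost=total / horizon_years,
        discount_rate=rate,
        horizon_years=horizon_years,
        pathway_component=pathway_component,
        drug_component=drug_component,
    )


def therapy_cost_breakdown(
    therapy_id: str,
    uses: Sequence[ResourceUse],
    costs: Iterable[UnitCost] | Mapping[str, UnitCost],
    regimen: DrugRegimen | None,
    horizon_years: int = 5,
    rate: float = 0.035,
    timing: str = "start_of_year",
) -> CostBreakdown:
    """Full cost breakdown for one therapy from its resource-use rows.

    Follow-up items (phase ``followup`` in the unit-cost table) are
    spread over the horizon; pre-treatment and procedure items fall at
    t = 0.  Therapies without a drug regimen (e.g. neurostimulation
    devices) have a zero drug component.
    """
    lookup = _cost_lookup(costs)
    mine = [u for u in uses if u.therapy_id == therapy_id]
    if not mine:
        raise CostingError(f"no resource-use rows for therapy {therapy_id!r}")
    full = pathway_cost(mine, lookup)
    followup = pathway_cost(
        [u for u in mine if lookup[u.item_id].phase == "followup"], lookup
    )
    drug = annual_drug_cost(regimen) if regimen is not None else 0.0
    return total_cost(
        full,
        drug,
        horizon_years,
        rate,
        timing,
        pathway_followup=followup,
        therapy_id=therapy_id,
    )


def read_table(path: str | Path, locale: str = "en_US", **kwargs) -> pd.DataFrame:
    """Read a CSV/TSV table honouring the locale's decimal convention."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if locale == "es_ES":
        if sep == ",":
            sep = ";"  # es_ES CSVs use ';' since ',' is the decimal mark
        return pd.read_csv(path, sep=sep, decimal=",", thousands=".", **kwargs)
    return pd.read_csv(path, sep=sep, **kwargs)
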