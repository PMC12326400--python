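"""Packaged input tables for the seven-therapy advanced-PD analysis.

The bundle transcribes the Spanish SNS unit-cost/resource-use table
(EUR 2023), the standard-dose drug regimens priced at PVL, and the
per-therapy discounted effect summaries (life-years and QALYs) for:
continuous subcutaneous apomorphine infusion (Apo-Go, Dacepton), deep
brain stimulation (Percept PC, Percept RC), levodopa-carbidopa
intestinal gel (Duodopa), foslevodopa/foscarbidopa subcutaneous
infusion (Foslevodopa) and levodopa-carbidopa-entacapone intestinal
gel (Lecigon).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .costing import DrugRegimen, ResourceUse, UnitCost

__all__ = ["TherapyBundle", "load_advanced_pd", "write_fixture", "THERAPY_IDS"]

THERAPY_IDS = (
    "apogo",
    "dacepton",
    "percept_pc",
    "percept_rc",
    "duodopa",
    "foslevodopa",
    "lecigon",
)

DEFAULT_WTP = (22_000.0, 25_000.0, 60_000.0)  # EUR/QALY: standard band + special cap

_FILES = ("unit_costs.csv", "resource_use.csv", "regimens.csv", "effects.csv")


def _read(name: str) -> pd.DataFrame:
    with resources.files("pdcea.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass
class TherapyBundle:
    """Raw input tables plus typed accessors."""

    unit_costs: pd.DataFrame
    resource_use: pd.DataFrame
    regimens: pd.DataFrame
    effects: pd.DataFrame

    @property
    def therapy_ids(self) -> list[str]:
        return list(self.effects["therapy_id"])

    def unit_cost_objects(self) -> dict[str, UnitCost]:
        return {
            r.item_id: UnitCost(
                item_id=r.item_id,
                label=r.label,
                unit_cost=float(r.unit_cost),
                source_year=int(r.source_year),
                phase=r.phase,
            )
            for r in self.unit_costs.itertuples()
        }

    def resource_use_objects(self, therapy_id: str | None = None) -> list[ResourceUse]:
        df = self.resource_use
        if therapy_id is not None:
            df = df[df["therapy_id"] == therapy_id]
        return [
            ResourceUse(r.therapy_id, r.item_id, float(r.count))
            for r in df.itertuples()
        ]

    def regimen(self, therapy_id: str) -> DrugRegimen | None:
        df = self.regimens[self.regimens["therapy_id"] == therapy_id]
        if df.empty:
            return None  # DBS strategies carry no drug regimen
        r = df.iloc[0]
        return DrugRegimen(
            therapy_id=r["therapy_id"],
            national_code=str(r["national_code"]),
            pack_price=float(r["pack_price"]),
            dose_per_standard_unit=float(r["dose_per_standard_unit"]),
            cost_per_standard_unit=float(r["cost_per_standard_unit"]),
            standard_units_per_day=float(r["standard_units_per_day"]),
            daily_dose_mg=float(r["daily_dose_mg"]),
        )

    def effect_targets(self) -> pd.DataFrame:
        """Per-therapy discounted life-year / QALY targets."""
        return self.effects[["therapy_id", "life_years", "qalys"]].copy()

    def implied_total_costs(self, measure: str = "qalys") -> pd.DataFrame:
        """Total per-therapy costs implied by the published average ratios.

        The source reports average cost-utility (ACU, EUR/QALY) and
        cost-effectiveness (ACE, EUR/LY) ratios but not the underlying
        totals; multiplying the ratio by its effect recovers them
        (``qalys``: ACU x QALYs, ``life_years``: ACE x LY).  The two
        reconstructions differ by ~0.1% because the printed ratios are
        rounded to whole euros.
        """
        df = self.effects.copy()
        if measure == "qalys":
            df["total_cost"] = df["acu_eur_per_qaly"] * df["qalys"]
        elif measure == "life_years":
            df["total_cost"] = df["ace_eur_per_ly"] * df["life_years"]
        else:
            raise ValueError(f"unknown measure {measure!r}")
        return df[["therapy_id", "total_cost", "life_years", "qalys"]]


def load_advanced_pd() -> TherapyBundle:
    """Load the packaged seven-therapy input bundle."""
    return TherapyBundle(
        unit_costs=_read("unit_costs.csv"),
        resource_use=_read("resource_use.csv"),
        regimens=_read("regimens.csv"),
        effects=_read("effects.csv"),
    )


def write_fixture(out_dir: str | Path) -> list[Path]:
    """Copy the packaged tables to a user directory; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _FILES:
        target = out / name
        target.write_text(
            resources.files("pdcea.data").joinpath(name).read_text()
        )
        written.append(target)
    return written
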