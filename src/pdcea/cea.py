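"""Cost-effectiveness and cost-utility analytics.

Average ratios (ACE = cost / life-years, ACU = cost / QALYs),
incremental ratios (ICER / ICUR), strict and extended dominance, the
efficiency frontier, cost-utility plane coordinates, willingness-to-pay
classification and net monetary benefit.

Dominance can be assessed two ways: against the full strategy set
(``versus=None``, the textbook analysis: pairwise strict dominance then
iterative extended-dominance removal on the cost-sorted remainder) or
against a single comparator (``versus=<therapy_id>``), which is how
decision analyses anchored on a reference strategy report it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TherapyResult",
    "CEATableRow",
    "WTPBand",
    "ICEROutcome",
    "WTPClass",
    "average_ratios",
    "icer",
    "dominance_classify",
    "efficiency_frontier",
    "FrontierResult",
    "wtp_classify",
    "ce_plane_coordinates",
    "net_monetary_benefit",
    "CostUtilityAnalysis",
    "CEAResults",
]


class ICEROutcome(str, Enum):
    """Sentinels for incremental comparisons without a finite ratio."""

    A_DOMINATES = "a_dominates"
    B_DOMINATES = "b_dominates"
    COST_COMPARISON = "cost_comparison"  # identical effects and costs


class WTPClass(str, Enum):
    BELOW_LOWER = "below_lower"
    WITHIN_BAND = "within_band"
    ABOVE_BAND_BELOW_SPECIAL = "above_band_below_special"
    ABOVE_SPECIAL = "above_special"


@dataclass(frozen=True)
class TherapyResult:
    therapy_id: str
    total_cost: float
    life_years: float
    qalys: float

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValueError(f"{self.therapy_id}: negative total cost")
        if self.life_years <= 0:
            raise ValueError(f"{self.therapy_id}: life_years must be > 0")

    def effect(self, measure: str) -> float:
        if measure == "qalys":
            return self.qalys
        if measure == "life_years":
            return self.life_years
        raise ValueError(f"unknown measure {measure!r}")


@dataclass(frozen=True)
class WTPBand:
    """Willingness-to-pay band in EUR/QALY: a standard range plus a
    higher cap accepted in special situations."""

    lower: float = 22_000.0
    upper: float = 25_000.0
    special_upper: float = 60_000.0

    def __post_init__(self) -> None:
        if not self.lower <= self.upper <= self.special_upper:
            raise ValueError("WTP band requires lower <= upper <= special_upper")


@dataclass(frozen=True)
class CEATableRow:
    therapy_id: str
    acer_ly: float
    acur_qaly: float
    dominance: str = "nondominated"
    icur_vs_reference: float | str | None = None


def average_ratios(r: TherapyResult) -> CEATableRow:
    """Average cost-effectiveness (per LY) and cost-utility (per QALY)
    ratios; zero cost yields zero ratios."""
    acer = r.total_cost / r.life_years
    acur = r.total_cost / r.qalys if r.qalys > 0 else float("inf")
    if r.total_cost == 0:
        acur = 0.0
    return CEATableRow(therapy_id=r.therapy_id, acer_ly=acer, acur_qaly=acur)


def icer(
    a: TherapyResult, b: TherapyResult, measure: str = "qalys"
) -> float | ICEROutcome:
    """Incremental cost per unit effect of a versus b.

    Returns a sentinel instead of a ratio when one option dominates
    (cheaper and at least as effective, or equally effective and
    cheaper) or when the two are indistinguishable.
    """
    dc = a.total_cost - b.total_cost
    de = a.effect(measure) - b.effect(measure)
    if de == 0:
        if dc == 0:
            return ICEROutcome.COST_COMPARISON
        return ICEROutcome.B_DOMINATES if dc > 0 else ICEROutcome.A_DOMINATES
    if de > 0 and dc <= 0:
        return ICEROutcome.A_DOMINATES
    if de < 0 and dc >= 0:
        return ICEROutcome.B_DOMINATES
    return dc / de


def _strictly_dominates(
    a: TherapyResult, b: TherapyResult, measure: str
) -> bool:
    """a dominates b: costs no more, yields no less, at least one strict.
    Equal effect with higher cost counts as dominated."""
    dc = a.total_cost - b.total_cost
    de = a.effect(measure) - b.effect(measure)
    return dc <= 0 and de >= 0 and (dc < 0 or de > 0)


def dominance_classify(
    results: Sequence[TherapyResult],
    measure: str = "qalys",
    versus: str | None = None,
) -> dict[str, str]:
    """Label each therapy nondominated / dominated / extended_dominated.

    ``versus=None`` runs the full analysis: a pairwise strict-dominance
    pass over the whole set, then iterative extended-dominance removal
    on the cost-sorted survivors (a strategy is extended-dominated when
    a linear combination of two others delivers its effect more
    cheaply).  ``versus=<id>`` labels strategies dominated only when the
    named comparator itself dominates them.  Identical cost/effect pairs
    tie: neither dominates, with a warning.
    """
    if len(results) < 2:
        raise ValueError("dominance analysis needs at least 2 therapies")
    ids = [r.therapy_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate therapy ids")
    for a in results:
        for b in results:
            if (
                a.therapy_id < b.therapy_id
                and a.total_cost == b.total_cost
                and a.effect(measure) == b.effect(measure)
            ):
                warnings.warn(
                    f"{a.therapy_id} and {b.therapy_id} are identical on the "
                    f"cost/{measure} plane; neither dominates",
                    stacklevel=2,
                )
    labels = {r.therapy_id: "nondominated" for r in results}
    if versus is not None:
        ref = next((r for r in results if r.therapy_id == versus), None)
        if ref is None:
            raise ValueError(f"comparator {versus!r} not in results")
        for r in results:
            if r.therapy_id != versus and _strictly_dominates(ref, r, measure):
                labels[r.therapy_id] = "dominated"
        return labels
    for r in results:
        if any(
            _strictly_dominates(o, r, measure)
            for o in results
            if o.therapy_id != r.therapy_id
        ):
            labels[r.therapy_id] = "dominated"
    # extended dominance on the cost-sorted nondominated remainder
    frontier = sorted(
        (r for r in results if labels[r.therapy_id] == "nondominated"),
        key=lambda r: (r.effect(measure), r.total_cost),
    )
    changed = True
    while changed and len(frontier) >= 3:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = icer(mid, lo, measure)
            icer_hi = icer(hi, mid, measure)
            if isinstance(icer_lo, float) and isinstance(icer_hi, float):
                # strictly greater: a blend of lo and hi beats mid;
                # equal ICERs (collinear) keep mid by the declared tie rule
                if icer_lo > icer_hi:
                    labels[mid.therapy_id] = "extended_dominated"
                    del frontier[i]
                    changed = True
                    break
    return labels


@dataclass(frozen=True)
class FrontierResult:
    """Efficiency frontier: nondominated therapies by increasing effect
    with stepwise ICERs (the least effective carries none)."""

    therapy_ids: tuple[str, ...]
    effects: tuple[float, ...]
    costs: tuple[float, ...]
    stepwise_icers: tuple[float | None, ...]
    measure: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "therapy_id": self.therapy_ids,
                f"effect_{self.measure}": self.effects,
                "total_cost": self.costs,
                "stepwise_icer": [
                    np.nan if v is None else v for v in self.stepwise_icers
                ],
            }
        )


def efficiency_frontier(
    results: Sequence[TherapyResult], measure: str = "qalys"
) -> FrontierResult:
    """Nondominated strategies ordered by effect with stepwise ICERs."""
    labels = (
        dominance_classify(results, measure)
        if len(results) >= 2
        else {results[0].therapy_id: "nondominated"}
    )
    front = sorted(
        (r for r in results if labels[r.therapy_id] == "nondominated"),
        key=lambda r: (r.effect(measure), r.total_cost),
    )
    icers: list[float | None] = [None]
    for prev, cur in zip(front, front[1:]):
        step = icer(cur, prev, measure)
        icers.append(step if isinstance(step, float) else None)
    return FrontierResult(
        therapy_ids=tuple(r.therapy_id for r in front),
        effects=tuple(r.effect(measure) for r in front),
        costs=tuple(r.total_cost for r in front),
        stepwise_icers=tuple(icers),
        measure=measure,
    )


def wtp_classify(ratio: float | CEATableRow, band: WTPBand) -> WTPClass:
    """Classify a cost-utility ratio against a willingness-to-pay band.

    Accepts a ratio or a :class:`CEATableRow` (whose finite ICUR versus
    the reference, when present, takes precedence over the ACU).  A
    ratio exactly at an edge classifies into the lower category.
    """
    if isinstance(ratio, CEATableRow):
        value = ratio.acur_qaly
        if isinstance(ratio.icur_vs_reference, float):
            value = ratio.icur_vs_reference
    else:
        value = float(ratio)
    if value <= band.lower:
        return WTPClass.BELOW_LOWER
    if value <= band.upper:
        return WTPClass.WITHIN_BAND
    if value <= band.special_upper:
        return WTPClass.ABOVE_BAND_BELOW_SPECIAL
    return WTPClass.ABOVE_SPECIAL


def ce_plane_coordinates(
    results: Sequence[TherapyResult], reference_id: str
) -> pd.DataFrame:
    """Incremental (delta-QALY, delta-cost) coordinates versus the
    reference; the reference maps to (0, 0)."""
    ref = next((r for r in results if r.therapy_id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in results")
    return pd.DataFrame(
        {
            "therapy_id": [r.therapy_id for r in results],
            "delta_qalys": [r.qalys - ref.qalys for r in results],
            "delta_cost": [r.total_cost - ref.total_cost for r in results],
        }
    )


def net_monetary_benefit(r: TherapyResult, wtp: float) -> float:
    """NMB = wtp x QALYs - cost (EUR)."""
    return wtp * r.qalys - r.total_cost


class CostUtilityAnalysis:
    """Cost-utility analysis of a strategy set.

    Parameters
    ----------
    results : sequence of TherapyResult or DataFrame
        Per-therapy totals; a DataFrame needs columns ``therapy_id``,
        ``total_cost``, ``life_years``, ``qalys``.
    reference : str
        Therapy id for the incremental analysis, or ``"auto"`` to take
        the lowest-ACU strategy.
    wtp_band : WTPBand
    measure : str
        Effect measure for dominance/frontier: ``"qalys"`` (default) or
        ``"life_years"``.
    dominance_versus : {"reference", "all"}
        Anchor dominance on the reference strategy (how analyses built
        around a single comparator report it) or on the full pairwise +
        extended analysis.
    """

    def __init__(
        self,
        results: Sequence[TherapyResult] | pd.DataFrame,
        reference: str = "auto",
        wtp_band: WTPBand | None = None,
        measure: str = "qalys",
        dominance_versus: str = "reference",
    ):
        if isinstance(results, pd.DataFrame):
            results = [
                TherapyResult(
                    therapy_id=str(r.therapy_id),
                    total_cost=float(r.total_cost),
                    life_years=float(r.life_years),
                    qalys=float(r.qalys),
                )
                for r in results.itertuples()
            ]
        self.results = list(results)
        if not self.results:
            raise ValueError("empty result set")
        self.reference = reference
        self.wtp_band = wtp_band or WTPBand()
        self.measure = measure
        if dominance_versus not in ("reference", "all"):
            raise ValueError("dominance_versus must be 'reference' or 'all'")
        self.dominance_versus = dominance_versus

    def fit(self) -> "CEAResults":
        rows = {r.therapy_id: average_ratios(r) for r in self.results}
        if self.reference == "auto":
            ref_id = min(rows.values(), key=lambda row: row.acur_qaly).therapy_id
        else:
            ref_id = self.reference
            if ref_id not in rows:
                raise ValueError(f"reference {ref_id!r} not in results")
        versus = ref_id if self.dominance_versus == "reference" else None
        labels = dominance_classify(self.results, self.measure, versus=versus)
        ref = next(r for r in self.results if r.therapy_id == ref_id)
        out = []
        for r in self.results:
            row = rows[r.therapy_id]
            if r.therapy_id == ref_id:
                inc: float | str | None = "reference"
            elif labels[r.therapy_id] != "nondominated":
                inc = "dominated"
            else:
                step = icer(r, ref, self.measure)
                inc = step if isinstance(step, float) else step.value
            out.append(
                replace(row, dominance=labels[r.therapy_id], icur_vs_reference=inc)
            )
        frontier = efficiency_frontier(self.results, self.measure)
        plane = ce_plane_coordinates(self.results, ref_id)
        return CEAResults(
            model=self,
            rows=out,
            reference_id=ref_id,
            frontier=frontier,
            ce_plane=plane,
        )


@dataclass
class CEAResults:
    """Fitted cost-utility analysis: table, frontier and CE plane."""

    model: CostUtilityAnalysis
    rows: list[CEATableRow]
    reference_id: str
    frontier: FrontierResult
    ce_plane: pd.DataFrame

    def table(self, include_nmb: bool = False) -> pd.DataFrame:
        by_id = {r.therapy_id: r for r in self.model.results}
        df = pd.DataFrame(
            {
                "therapy_id": [row.therapy_id for row in self.rows],
                "total_cost": [by_id[row.therapy_id].total_cost for row in self.rows],
                "life_years": [by_id[row.therapy_id].life_years for row in self.rows],
                "qalys": [by_id[row.therapy_id].qalys for row in self.rows],
                "ace_eur_per_ly": [row.acer_ly for row in self.rows],
                "acu_eur_per_qaly": [row.acur_qaly for row in self.rows],
                "dominance": [row.dominance for row in self.rows],
                "icur_vs_reference": [row.icur_vs_reference for row in self.rows],
                "wtp_class": [
                    wtp_classify(row, self.model.wtp_band).value for row in self.rows
                ],
            }
        )
        if include_nmb:
            lam = self.model.wtp_band.upper
            df["nmb_eur"] = [
                net_monetary_benefit(by_id[row.therapy_id], lam) for row in self.rows
            ]
        return df

    def summary(self) -> str:
        df = self.table()
        dominated = df.loc[df["dominance"] != "nondominated", "therapy_id"].tolist()
        lines = [
            "Cost-utility analysis",
            "---------------------",
            f"strategies:  {len(df)}",
            f"reference:   {self.reference_id} (lowest ACU)",
            f"measure:     {self.model.measure}",
            f"dominated:   {', '.join(dominated) if dominated else 'none'}",
            "",
        ]
        show = df.copy()
        for col in ("total_cost", "ace_eur_per_ly", "acu_eur_per_qaly"):
            show[col] = show[col].round(0).astype(int)
        show["icur_vs_reference"] = [
            f"{v:,.0f}" if isinstance(v, float) else v
            for v in df["icur_vs_reference"]
        ]
        lines.append(show.to_string(index=False))
        return "\n".join(lines)
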