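"""End-to-end pipeline: costing -> cost-utility analysis -> report files.

Outputs are deterministic given identical configuration, inputs and
seed: dot-decimal CSVs plus a provenance JSON (configuration echo,
package version, input checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import CostUtilityAnalysis, WTPBand
from .costing import therapy_cost_breakdown
from .datasets import TherapyBundle, load_advanced_pd
from .synthetic import CalibrationTarget, TherapyCalibration

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report_tables"]


class PipelineError(RuntimeError):
    """Raised when pipeline inputs are missing or invalid."""


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``total_cost_basis`` selects the per-therapy totals fed to the CEA:
    ``"implied"`` reconstructs them from the published average
    cost-utility ratios (ratio x effect), which is the basis on which
    the source's dominance and incremental results rest; ``"computed"``
    uses this package's own discounted pathway + drug costing.
    """

    locale: str = "en_US"
    discount_rate: float = 0.035
    horizon_years: int = 5
    effect_horizon_years: int = 20
    reference_therapy: str = "auto"
    wtp_band: WTPBand = field(default_factory=WTPBand)
    seed: int = 0
    output_dir: str = "pdcea_out"
    total_cost_basis: str = "implied"
    perspective: str = "Spanish National Health System (SNS)"
    dominance_versus: str = "reference"

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years < 1 or self.effect_horizon_years < 1:
            raise ValueError("horizons must be >= 1")
        if self.total_cost_basis not in ("implied", "computed"):
            raise ValueError("total_cost_basis must be 'implied' or 'computed'")


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def compute_cost_table(bundle: TherapyBundle, config: RunConfig) -> pd.DataFrame:
    """Per-therapy cost breakdown from the resource and regimen tables."""
    if bundle.resource_use.empty:
        raise PipelineError("resource-use table is empty")
    rows = []
    uses = bundle.resource_use_objects()
    costs = bundle.unit_cost_objects()
    for tid in bundle.therapy_ids:
        bd = therapy_cost_breakdown(
            tid,
            uses,
            costs,
            bundle.regimen(tid),
            horizon_years=config.horizon_years,
            rate=config.discount_rate,
        )
        rows.append(
            {
                "therapy_id": tid,
                "pathway_cost_5y": bd.pathway_cost_5y,
                "drug_cost_annual": bd.drug_cost_annual,
                "discounted_total_cost": bd.total_cost,
                "average_annual_cost": bd.average_annual_cost,
            }
        )
    return pd.DataFrame(rows)


def therapy_totals(bundle: TherapyBundle, config: RunConfig) -> pd.DataFrame:
    """therapy_id / total_cost / life_years / qalys under the configured basis."""
    if config.total_cost_basis == "implied":
        return bundle.implied_total_costs(measure="qalys")
    cost = compute_cost_table(bundle, config)[
        ["therapy_id", "discounted_total_cost"]
    ].rename(columns={"discounted_total_cost": "total_cost"})
    return cost.merge(bundle.effect_targets(), on="therapy_id")


def run_pipeline(
    config: RunConfig,
    bundle: TherapyBundle | None = None,
    calibrate: bool = False,
    plot: bool = False,
) -> dict[str, Path]:
    """Run costing + CEA (and optionally calibration) and write reports.

    Returns a mapping of artifact name to written path.
    """
    if bundle is None:
        bundle = load_advanced_pd()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cost_table = compute_cost_table(bundle, config)
    totals = therapy_totals(bundle, config)
    analysis = CostUtilityAnalysis(
        totals,
        reference=config.reference_therapy,
        wtp_band=config.wtp_band,
        dominance_versus=config.dominance_versus,
    )
    res = analysis.fit()
    cea_table = res.table()

    written["costs"] = out / "costs.csv"
    cost_table.to_csv(written["costs"], index=False, float_format="%.6f")
    written["cea_table"] = out / "cea_table.csv"
    cea_table.to_csv(written["cea_table"], index=False, float_format="%.6f")
    written["frontier"] = out / "frontier.csv"
    res.frontier.to_frame().to_csv(written["frontier"], index=False, float_format="%.6f")
    written["ce_plane"] = out / "ce_plane.csv"
    res.ce_plane.to_csv(written["ce_plane"], index=False, float_format="%.6f")

    if calibrate:
        cal_rows = []
        for r in bundle.effect_targets().itertuples():
            result = TherapyCalibration(
                CalibrationTarget(r.therapy_id, r.life_years, r.qalys),
                rate=config.discount_rate,
                n_cycles=config.effect_horizon_years,
            ).fit()
            e_ly, e_q = result.relative_errors
            cal_rows.append(
                {
                    "therapy_id": r.therapy_id,
                    "mortality_hazard": result.mortality_hazard,
                    "utility_scale": result.utility_scale,
                    "life_years": result.achieved.life_years,
                    "qalys": result.achieved.qalys,
                    "rel_err_life_years": e_ly,
                    "rel_err_qalys": e_q,
                }
            )
        written["calibration"] = out / "calibration.csv"
        pd.DataFrame(cal_rows).to_csv(
            written["calibration"], index=False, float_format="%.8f"
        )

    if plot:
        from .plotting import plot_ce_plane

        written["ce_plane_plot"] = out / "ce_plane.svg"
        plot_ce_plane(res, path=written["ce_plane_plot"])

    prov = {
        "package": "pdcea",
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "wtp_band"},
            "wtp_band": asdict(config.wtp_band),
        },
        "input_checksums": {
            "unit_costs": _checksum(bundle.unit_costs),
            "resource_use": _checksum(bundle.resource_use),
            "regimens": _checksum(bundle.regimens),
            "effects": _checksum(bundle.effects),
        },
        "reference_therapy": res.reference_id,
    }
    written["provenance"] = out / "provenance.json"
    written["provenance"].write_text(json.dumps(prov, indent=2, sort_keys=True))
    return written


def report_tables(cea_table: pd.DataFrame, fmt: str = "csv") -> str:
    """Presentation-layer report: euro columns rounded to whole euros.

    Rounding happens only here; upstream values stay unrounded.
    """
    if cea_table.empty:
        raise PipelineError("empty CEA table")
    df = cea_table.copy()
    for col in ("total_cost", "ace_eur_per_ly", "acu_eur_per_qaly"):
        if col in df:
            df[col] = df[col].round(0).astype(int)
    if "icur_vs_reference" in df:
        df["icur_vs_reference"] = [
            f"{v:.0f}" if isinstance(v, float) else v
            for v in df["icur_vs_reference"]
        ]
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "markdown":
        return df.to_markdown(index=False)
    raise ValueError(f"unknown format {fmt!r}")
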