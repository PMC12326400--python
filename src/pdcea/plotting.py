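"""Cost-utility plane plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_ce_plane(results, path: str | Path | None = None, wtp: float | None = None):
    """Incremental cost-utility plane versus the reference strategy.

    Each strategy is a point (delta-QALYs, delta-cost) relative to the
    reference at the origin; an optional willingness-to-pay line with
    slope ``wtp`` (EUR/QALY) is drawn through the origin.
    """
    plane = results.ce_plane
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.axhline(0, color="0.6", lw=0.8)
    ax.axvline(0, color="0.6", lw=0.8)
    for r in plane.itertuples():
        marker = "s" if r.therapy_id == results.reference_id else "o"
        ax.scatter(r.delta_qalys, r.delta_cost, marker=marker, zorder=3)
        ax.annotate(
            r.therapy_id,
            (r.delta_qalys, r.delta_cost),
            textcoords="offset points",
            xytext=(6, 4),
            fontsize=8,
        )
    if wtp is not None:
        lim = max(abs(plane["delta_qalys"]).max(), 0.1) * 1.1
        ax.plot([-lim, lim], [-wtp * lim, wtp * lim], "--", color="tab:red",
                lw=0.9, label=f"WTP {wtp:,.0f} EUR/QALY")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("Incremental QALYs vs reference")
    ax.set_ylabel("Incremental cost (EUR) vs reference")
    ax.set_title("Incremental cost-utility plane")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    return fig
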