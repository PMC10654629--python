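"""Standard figures: tornado diagram, CEAC, and cost-effectiveness plane."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import CEACCurve, OWSAResult, PSAResult

__all__ = ["tornado_plot", "ceac_plot", "ce_plane_plot"]


def tornado_plot(result: OWSAResult, path: str | Path, top: int = 15) -> None:
    entries = result.entries[:top][::-1]
    names = [e.name for e in entries]
    lows = [e.inmb_at_low for e in entries]
    highs = [e.inmb_at_high for e in entries]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        left, right = min(lo, hi), max(lo, hi)
        ax.barh(i, right - left, left=left, color="#4878d0", alpha=0.8)
    ax.axvline(result.base_inmb, color="k", lw=1, ls="--", label="base-case INMB")
    ax.set_yticks(range(len(entries)), names, fontsize=8)
    ax.set_xlabel("INMB (USD)")
    ax.set_title(f"One-way sensitivity analysis ({result.population}, ±{result.span:.0%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: CEACCurve, wtp_threshold: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, color="#4878d0")
    ax.axvline(wtp_threshold, color="k", lw=1, ls="--", label=f"WTP ${wtp_threshold:,.0f}/QALY")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(intervention cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(result: PSAResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.draws["delta_qalys"], result.draws["delta_cost"], s=6, alpha=0.4)
    grid_x = ax.get_xlim()
    ax.plot(grid_x, [result.wtp * x for x in grid_x], "k--", lw=1, label="WTP threshold")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title(f"Cost-effectiveness plane ({result.population})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
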