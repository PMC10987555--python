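"""Optional plot side-outputs (TSV reports are the contract, plots are views)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .forks import MetageneProfile
from .midas import RegionProfiles
from .origins import CorrelationSummary

CLASS_COLORS = {"CN": "#6a3d9a", "intermediate": "#ff7f00", "Oi": "#e31a1c"}


def plot_correlation(summary: CorrelationSummary, path: str | Path) -> None:
    """Per-class scatter of origin efficiencies in sample A vs sample B."""
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = 1.0
    for label, d in summary.classes.items():
        if d["n"] == 0:
            continue
        ax.scatter(
            d["eff_A"], d["eff_B"], s=8, alpha=0.7,
            color=CLASS_COLORS.get(label, "gray"),
            label=f"{label} (n={d['n']}, r={d['pearson_r']:.2f})",
        )
        lim = max(lim, float(np.max(d["eff_A"])), float(np.max(d["eff_B"])))
    ax.plot([0, lim], [0, lim], color="k", lw=0.5, ls="--")
    ax.set_xlabel("efficiency, sample A (sigma)")
    ax.set_ylabel("efficiency, sample B (sigma)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metagene(profiles: list[MetageneProfile], path: str | Path) -> None:
    """Overlayed metagene profiles, one line per release timepoint."""
    fig, ax = plt.subplots(figsize=(5, 3))
    for p in profiles:
        t = "?" if p.timepoint_min is None else f"{p.timepoint_min:g}"
        ax.plot(p.offsets / 1000.0, p.mean_asigma, label=f"{t} min")
    ax.set_xlabel("offset from origin (kb)")
    ax.set_ylabel("mean adjusted sigma")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_midas_heatmap(profiles: RegionProfiles, path: str | Path) -> None:
    """Average profile on top, per-region heatmap (display order) below."""
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(4, 6), height_ratios=[1, 3], sharex=True
    )
    ax0.plot(profiles.rel_axis, profiles.average)
    ax0.set_ylabel("mean sigma")
    im = ax1.imshow(
        profiles.matrix,
        aspect="auto",
        extent=(0, 1, len(profiles.matrix), 0),
        cmap="viridis",
    )
    ax1.set_xlabel("relative position")
    ax1.set_ylabel("region rank")
    fig.colorbar(im, ax=ax1, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
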