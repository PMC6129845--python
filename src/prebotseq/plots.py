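"""Figure panels for a completed run: timing CDFs, rank occupancies,
cumulative rank curves and leader fractions, one PNG per panel family."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cell_typing import FIVE_TYPES
from .group_stats import SequenceSummary

_COLORS = {
    "R-Ex": "#1b7837",
    "R-Gly": "#2166ac",
    "Irr-Ex": "#7fbf7b",
    "Irr-Gly": "#92c5de",
    "Irr-Cotrans": "#d9a400",
}


def plot_summary(summary: SequenceSummary, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.asarray(summary.occupancy_mean.columns, dtype=float)
    for t in FIVE_TYPES:
        ax.errorbar(
            bins, summary.occupancy_mean.loc[t], yerr=summary.occupancy_se.loc[t],
            label=t, color=_COLORS[t], marker="o", ms=3, capsize=2,
        )
    ax.set_xlabel("percent rank of activation order (bin upper edge)")
    ax.set_ylabel("share of activations in bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "fig_rank_occupancy.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for t in FIVE_TYPES:
        ax.errorbar(
            bins, summary.type_cumulative_mean.loc[t],
            yerr=summary.type_cumulative_se.loc[t],
            label=t, color=_COLORS[t], marker="o", ms=3, capsize=2,
        )
    ax.set_xlabel("percent rank of activation order (bin upper edge)")
    ax.set_ylabel("cumulative activation probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "fig_cumulative_rank.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    means = summary.mean_timing["mean_s"] * 1000.0
    ses = summary.mean_timing["se_s"] * 1000.0
    ax.bar(range(len(FIVE_TYPES)), [means[t] for t in FIVE_TYPES],
           yerr=[ses[t] for t in FIVE_TYPES],
           color=[_COLORS[t] for t in FIVE_TYPES], capsize=3)
    ax.set_xticks(range(len(FIVE_TYPES)), FIVE_TYPES, rotation=30)
    ax.set_ylabel("mean activation timing (ms after LFP peak)")
    fig.tight_layout()
    p = out_dir / "fig_mean_timing.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    lf = summary.leader_fractions
    ax.bar(range(len(FIVE_TYPES)), [lf.loc[t, "mean"] for t in FIVE_TYPES],
           yerr=[lf.loc[t, "se"] for t in FIVE_TYPES],
           color=[_COLORS[t] for t in FIVE_TYPES], capsize=3)
    ax.set_xticks(range(len(FIVE_TYPES)), FIVE_TYPES, rotation=30)
    ax.set_ylabel("fraction of cycles led by type")
    fig.tight_layout()
    p = out_dir / "fig_leader_fractions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
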