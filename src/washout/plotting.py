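"""Optional figures: NMDS scatter and steady-state retention boxplots.

Plots are convenience renderings of the numeric tables the pipeline writes;
the TSVs are the contract, the images are not.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .community import OrdinationResult

__all__ = ["nmds_scatter", "ratio_boxplots"]


def nmds_scatter(result: OrdinationResult, meta: pd.DataFrame, path: str | Path) -> None:
    """Scatter the first two NMDS axes, colored by reactor, open/filled by compartment."""
    coords = result.frame().join(meta.set_index("sample_id"))
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {r: c for r, c in zip(sorted(coords["reactor"].unique()), "C0 C1 C2 C3 C4".split())}
    for (reactor, compartment), grp in coords.groupby(["reactor", "compartment"]):
        ax.scatter(
            grp["axis1"],
            grp["axis2"],
            label=f"{reactor} {compartment}",
            color=colors[reactor],
            marker="o" if compartment == "granular" else "^",
            alpha=0.8,
        )
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.set_title(f"NMDS (stress = {result.stress:.3f})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ratio_boxplots(points: pd.DataFrame, reactor: str, path: str | Path) -> None:
    """Tukey boxplots of steady-state retention ratios per taxon for one reactor.

    ``points`` is the long-format retention series table (columns taxon,
    reactor, day, ratio, phase).
    """
    sel = points[(points["reactor"] == reactor) & (points["phase"] == "steady")]
    sel = sel[sel["ratio"].notna()]
    taxa = sorted(sel["taxon"].unique())
    data = [sel.loc[sel["taxon"] == t, "ratio"].to_numpy() for t in taxa]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(taxa)), 4))
    ax.boxplot(data, tick_labels=taxa, whis=1.5)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yscale("log")
    ax.set_ylabel("retention ratio (granular / effluent)")
    ax.set_title(f"{reactor}: steady-state retention ratios")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
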