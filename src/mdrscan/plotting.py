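"""Figure helpers: constraint violins, density profiles, rank histograms."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dnds import GeneConstraint
from .mdr_scan import variant_density_profile
from .prioritiser import RankedCandidate
from .variant_model import MISSENSE, SYNONYMOUS, CodingTranscript, VariantSite

__all__ = ["violin_dnds", "density_profile_plot", "rank_histogram"]


def violin_dnds(
    constraints: Sequence[GeneConstraint],
    labels: Mapping[str, str],
    out: Optional[str] = None,
):
    """Violin plot of per-gene dN/dS by category (inheritance pattern etc.)."""
    groups: dict[str, list[float]] = {}
    for c in constraints:
        cat = labels.get(c.gene_symbol)
        if cat is not None and c.dnds is not None:
            groups.setdefault(cat, []).append(c.dnds)
    cats = sorted(groups)
    fig, ax = plt.subplots(figsize=(1.6 * max(len(cats), 2) + 1, 4))
    ax.violinplot([groups[c] for c in cats], showmedians=True)
    ax.set_xticks(range(1, len(cats) + 1), cats)
    ax.set_ylabel("dN/dS")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def density_profile_plot(
    tx: CodingTranscript,
    variants: Sequence[VariantSite],
    window_bp: int = 90,
    out: Optional[str] = None,
):
    """Missense and synonymous site density along the CDS."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for cls, color in ((MISSENSE, "crimson"), (SYNONYMOUS, "steelblue")):
        prof = variant_density_profile(tx, variants, var_class=cls, window_bp=window_bp)
        ax.plot(prof["window_start"], prof["count"], label=cls, color=color, lw=1)
    ax.set_xlabel(f"CDS position ({tx.transcript_id})")
    ax.set_ylabel(f"sites / {window_bp} bp")
    ax.legend(frameon=False)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def rank_histogram(
    constraints: Sequence[GeneConstraint],
    candidates: Sequence[RankedCandidate],
    score: str = "dnds",
    out: Optional[str] = None,
    highlight: int = 3,
):
    """All-gene score histogram with proband genes as vertical lines."""
    values = np.array([getattr(c, score) for c in constraints if getattr(c, score) is not None])
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.hist(values, bins=50, color="lightgrey", edgecolor="grey")
    attr = "dnds_value" if score == "dnds" else "emd_value"
    rank_attr = "dnds_rank" if score == "dnds" else "emd_rank"
    ordered = sorted(
        (c for c in candidates if getattr(c, attr) is not None),
        key=lambda c: getattr(c, rank_attr),
    )
    for i, c in enumerate(ordered):
        top = i < highlight
        ax.axvline(
            getattr(c, attr),
            color="crimson" if top else "grey",
            lw=1.4 if top else 0.6,
            alpha=1.0 if top else 0.4,
        )
        if top:
            ax.text(
                getattr(c, attr), ax.get_ylim()[1] * (0.95 - 0.07 * i),
                c.gene_symbol, color="crimson", fontsize=8, ha="left",
            )
    ax.set_xlabel(score)
    ax.set_ylabel("genes")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
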