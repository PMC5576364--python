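"""Nei-Gojobori potential-site counting and per-gene dN/dS from population variants.

Potential sites are counted per codon: at each of the three codon positions the
fraction f of the three possible substitutions that are synonymous accrues to S
and 1-f to N, so every codon contributes exactly 3 sites split between the two
classes.  Stop-creating changes count toward N.  Observed counts are distinct
variant *sites* (CDS positions carrying at least one allele of the class), and
dN/dS is the raw proportion ratio (n/N)/(s/S) — population variants are rare,
so no multiple-hit (Jukes-Cantor) correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import (
    BASES,
    CLS_SYN,
    CLS_TABLE,
    MISSENSE,
    SYNONYMOUS,
    CodingTranscript,
    VariantSite,
    classify_substitution,
    codon_indices,
    IS_STOP64,
)

__all__ = [
    "GeneConstraint",
    "codon_potential_sites",
    "transcript_potential_sites",
    "genic_dnds",
    "compare_gene_sets",
    "GeneSetComparison",
]

# per-codon (N, S) for the 61 sense codons, derived once from the class table
_S64 = (CLS_TABLE == CLS_SYN).sum(axis=(1, 2)) / 3.0
_N64 = 3.0 - _S64


@dataclass
class GeneConstraint:
    """Per-transcript constraint summary: potential sites, observed sites, scores."""

    transcript_id: str
    gene_symbol: str
    cds_len: int
    N_sites: float
    S_sites: float
    n_obs: int
    s_obs: int
    dnds: Optional[float] = None
    emd: Optional[float] = None
    flags: set[str] = field(default_factory=set)


def codon_potential_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori potential nonsynonymous (N) and synonymous (S) sites of a codon.

    N + S == 3 for every sense codon.  Stop codons are rejected: the terminal
    stop contributes no sites and internal stops are handled by the caller.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    from .variant_model import CODON_TO_AA

    if CODON_TO_AA[codon] == "*":
        raise ValueError(f"potential sites are defined for sense codons, got stop {codon}")
    n = s = 0.0
    for off in range(3):
        syn = sum(
            1
            for b in BASES
            if b != codon[off] and classify_substitution(codon, off, b) == SYNONYMOUS
        )
        s += syn / 3.0
        n += 1.0 - syn / 3.0
    return n, s


def transcript_potential_sites(tx: CodingTranscript) -> tuple[float, float]:
    """Sum codon potential sites over the CDS, excluding the terminal stop codon.

    Internal stop codons (flagged transcripts) contribute no sites.
    """
    cod = codon_indices(tx)[:-1]
    sense = ~IS_STOP64[cod]
    return float(_N64[cod[sense]].sum()), float(_S64[cod[sense]].sum())


def observed_site_counts(variants: Iterable[VariantSite]) -> tuple[int, int]:
    """Distinct missense and synonymous variant site counts.

    A CDS position with both a synonymous and a missense alt contributes to
    both counts.  Nonsense/stop_lost/start_lost variants count in neither.
    """
    mis: set[int] = set()
    syn: set[int] = set()
    for v in variants:
        if v.consequence == MISSENSE:
            mis.add(v.cds_pos)
        elif v.consequence == SYNONYMOUS:
            syn.add(v.cds_pos)
    return len(mis), len(syn)


def genic_dnds(
    tx: CodingTranscript,
    variants: Sequence[VariantSite],
    min_variants: int = 1,
    pseudocount: bool = False,
) -> GeneConstraint:
    """Per-transcript dN/dS = (n/N)/(s/S) from population variant sites.

    dN/dS is undefined (``low_synonymous`` flag) when s_obs == 0, or when
    n_obs + s_obs < ``min_variants``.  With ``pseudocount`` 0.5 is added to all
    four counts and a value is always produced.
    """
    for v in variants:
        if v.transcript_id != tx.transcript_id:
            raise ValueError(
                f"variant on {v.transcript_id} passed to transcript {tx.transcript_id}"
            )
    n_total, s_total = transcript_potential_sites(tx)
    n_obs, s_obs = observed_site_counts(variants)
    flags: set[str] = set()
    if tx.has_internal_stop:
        flags.add("internal_stop")
    dnds: Optional[float] = None
    if pseudocount:
        dnds = ((n_obs + 0.5) / (n_total + 0.5)) / ((s_obs + 0.5) / (s_total + 0.5))
    elif s_obs == 0 or (n_obs + s_obs) < min_variants:
        flags.add("low_synonymous")
    else:
        dnds = (n_obs / n_total) / (s_obs / s_total)
        if n_obs == 0:
            flags.add("no_missense")
    return GeneConstraint(
        transcript_id=tx.transcript_id,
        gene_symbol=tx.gene_symbol,
        cds_len=len(tx.cds_seq),
        N_sites=n_total,
        S_sites=s_total,
        n_obs=n_obs,
        s_obs=s_obs,
        dnds=dnds,
        flags=flags,
    )


@dataclass
class GeneSetComparison:
    """Rank-test comparison of dN/dS between gene categories."""

    test: str  # "wilcoxon" (two-sample rank sum) or "kruskal"
    statistic: float
    pvalue: float
    summaries: pd.DataFrame  # index: category; columns n, median, q1, q3
    excluded: list[str]  # genes without a defined dN/dS


def compare_gene_sets(
    constraints: Iterable[GeneConstraint],
    labels: Mapping[str, str],
) -> GeneSetComparison:
    """Compare dN/dS distributions between gene categories.

    ``labels`` maps gene symbol -> category (e.g. inheritance pattern).  Genes
    without a defined dN/dS are excluded and reported.  Two categories use the
    two-sample Wilcoxon rank-sum test; more use Kruskal-Wallis.
    """
    groups: dict[str, list[float]] = {}
    excluded: list[str] = []
    for c in constraints:
        cat = labels.get(c.gene_symbol)
        if cat is None:
            continue
        if c.dnds is None:
            excluded.append(c.gene_symbol)
            continue
        groups.setdefault(cat, []).append(c.dnds)
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError(
            f"need >=2 categories with >=2 scored genes each, got {len(usable)}"
        )
    rows = {
        cat: {
            "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }
        for cat, v in sorted(usable.items())
    }
    summaries = pd.DataFrame.from_dict(rows, orient="index")
    samples = [usable[k] for k in sorted(usable)]
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = "wilcoxon"
    else:
        res = stats.kruskal(*samples)
        test = "kruskal"
    return GeneSetComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        summaries=summaries,
        excluded=sorted(excluded),
    )
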