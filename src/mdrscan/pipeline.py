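"""High-level workflows chaining the scoring modules.

These are the two analyses a user actually runs: score every transcript of an
exome against population variation (dN/dS + EMD + MDR scan), and prioritise a
proband's rare variants against those genome-wide scores.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .dnds import GeneConstraint, genic_dnds
from .emd_score import gene_emd
from .mdr_scan import MDRInterval, scan_mdr
from .prioritiser import (
    RankedCandidate,
    annotate_trio,
    filter_rare_coding,
    rank_candidates,
)
from .variant_model import CodingTranscript, VariantSite

__all__ = ["score_transcripts", "prioritise"]


def score_transcripts(
    transcripts: Mapping[str, CodingTranscript],
    variants_by_tx: Mapping[str, Sequence[VariantSite]],
    emd_min_sites: int = 3,
    pseudocount: bool = False,
    min_variants: int = 1,
    scan: bool = False,
    **scan_params,
) -> tuple[list[GeneConstraint], list[MDRInterval]]:
    """Per-transcript constraint scores (dN/dS and EMD), optionally with MDRs.

    Transcripts whose EMD is undefined (fewer than ``emd_min_sites`` distinct
    sites in either class) get the ``few_sites_emd`` flag.
    """
    constraints: list[GeneConstraint] = []
    intervals: list[MDRInterval] = []
    for tid in sorted(transcripts):
        tx = transcripts[tid]
        vs = variants_by_tx.get(tid, ())
        c = genic_dnds(tx, vs, min_variants=min_variants, pseudocount=pseudocount)
        c.emd = gene_emd(tx, vs, min_sites=emd_min_sites)
        if c.emd is None:
            c.flags.add("few_sites_emd")
        constraints.append(c)
        if scan and not tx.has_internal_stop:
            intervals.extend(scan_mdr(tx, vs, **scan_params))
    return constraints, intervals


def prioritise(
    proband: Sequence[VariantSite],
    constraints: Sequence[GeneConstraint],
    mdrs: Sequence[MDRInterval] = (),
    mother: Optional[Sequence[VariantSite]] = None,
    father: Optional[Sequence[VariantSite]] = None,
    transcripts: Optional[Mapping[str, CodingTranscript]] = None,
    maf_threshold: float = 0.01,
    proband_sex: str = "unknown",
    proband_only: bool = False,
) -> list[RankedCandidate]:
    """Filter, rank and (when parents are given) trio-annotate proband variants.

    Trio annotation fills only the inheritance column; scores and ranks are
    identical with or without parental data.
    """
    filtered = filter_rare_coding(proband, maf_threshold=maf_threshold)
    candidates = rank_candidates(filtered, constraints, mdrs, proband_only=proband_only)
    gene_of = {c.transcript_id: c.gene_symbol for c in constraints}
    classes = annotate_trio(
        filtered,
        mother,
        father,
        transcripts=transcripts,
        gene_of=gene_of,
        proband_sex=proband_sex,
    )
    for cand in candidates:
        cand.inheritance = classes.get(cand.variant.key, "unknown")
    return candidates
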