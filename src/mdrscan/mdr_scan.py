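"""Missense-depleted region (MDR) scanning.

An MDR is a contiguous CDS stretch of at least ``min_length`` base pairs that
contains no missense variant site in population data yet retains synonymous
variation: at least ``min_syn`` synonymous sites and an aggregate density of
one synonymous site per 10-codon (30 bp) group.  Candidate intervals are the
maximal missense-free stretches between consecutive missense sites (and the
CDS ends) — equivalent to a sliding-window scan under these criteria but with
canonical boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_model import (
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    CodingTranscript,
    VariantSite,
    project_cds_interval_to_genomic,
)

__all__ = [
    "MDRInterval",
    "scan_mdr",
    "scan_genome",
    "mdr_size_sweep",
    "variant_density_profile",
    "mdr_table",
]

DEFAULT_MIN_LENGTH = 300
DEFAULT_MIN_SYN = 10
DEFAULT_DENSITY_FLOOR = 1.0 / 30.0  # one synonymous site per 10-codon group


@dataclass
class MDRInterval:
    """A missense-free CDS interval passing the length/synonymous criteria.

    ``cds_start``/``cds_end`` are 0-based half-open; a variant at 1-based CDS
    position p lies inside iff cds_start <= p - 1 < cds_end.
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    syn_count: int
    genomic_blocks: Optional[list[tuple[str, int, int]]] = None

    @property
    def length_bp(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def syn_density(self) -> float:
        return self.syn_count / self.length_bp

    def contains(self, cds_pos: int) -> bool:
        return self.cds_start <= cds_pos - 1 < self.cds_end


def _density_ok(syn_count: int, length: int, density_floor: float) -> bool:
    # aggregate floor, rounded down to whole sites: a 610 bp region needs
    # floor(610/30) = 20 synonymous sites at the default floor.
    return syn_count >= math.floor(length * density_floor + 1e-9)


def _strict_blocks_ok(
    syn_pos0: np.ndarray, start: int, end: int, block_bp: int
) -> bool:
    for b in range(start, end - block_bp + 1, block_bp):
        if not np.any((syn_pos0 >= b) & (syn_pos0 < b + block_bp)):
            return False
    return True


def scan_mdr(
    tx: CodingTranscript,
    variants: Sequence[VariantSite],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_syn: int = DEFAULT_MIN_SYN,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
    break_on_nonsense: bool = False,
    strict_blocks: bool = False,
    project: bool = True,
) -> list[MDRInterval]:
    """Scan one transcript for missense-depleted regions.

    Candidates are maximal missense-free stretches; boundaries are the base
    after/before the flanking missense sites (the missense positions themselves
    excluded).  Each candidate is kept iff it is at least ``min_length`` bp,
    carries at least ``min_syn`` synonymous sites, and meets the aggregate
    density floor.  ``break_on_nonsense`` additionally lets nonsense sites
    terminate candidates; ``strict_blocks`` enforces one synonymous site in
    every complete 30 bp block instead of the aggregate floor.
    """
    if min_length < 3:
        raise ValueError(f"min_length must be >= 3, got {min_length}")
    if min_syn < 0 or density_floor < 0:
        raise ValueError("min_syn and density_floor must be non-negative")
    L = len(tx.cds_seq)
    breaking = {MISSENSE, NONSENSE} if break_on_nonsense else {MISSENSE}
    mis = sorted({v.cds_pos for v in variants if v.consequence in breaking})
    syn_pos0 = np.asarray(
        sorted({v.cds_pos - 1 for v in variants if v.consequence == SYNONYMOUS}),
        dtype=np.int64,
    )
    out: list[MDRInterval] = []
    for i in range(len(mis) + 1):
        start = 0 if i == 0 else mis[i - 1]  # 0-based: base after the missense site
        end = L if i == len(mis) else mis[i] - 1  # base before the next missense site
        length = end - start
        if length < min_length:
            continue
        syn_count = int(
            np.searchsorted(syn_pos0, end, side="left")
            - np.searchsorted(syn_pos0, start, side="left")
        )
        if syn_count < min_syn:
            continue
        if strict_blocks:
            block = max(3, int(round(1.0 / density_floor))) if density_floor > 0 else 30
            if not _strict_blocks_ok(syn_pos0, start, end, block):
                continue
        elif not _density_ok(syn_count, length, density_floor):
            continue
        blocks = None
        if project and tx.exon_blocks is not None:
            blocks = project_cds_interval_to_genomic(tx, start, end)
        out.append(
            MDRInterval(
                transcript_id=tx.transcript_id,
                cds_start=start,
                cds_end=end,
                syn_count=syn_count,
                genomic_blocks=blocks,
            )
        )
    return out


def mdr_table(intervals: Iterable[MDRInterval]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": iv.transcript_id,
            "cds_start": iv.cds_start,
            "cds_end": iv.cds_end,
            "length_bp": iv.length_bp,
            "syn_count": iv.syn_count,
            "syn_density": iv.syn_density,
        }
        for iv in intervals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "cds_start",
            "cds_end",
            "length_bp",
            "syn_count",
            "syn_density",
        ],
    )


def scan_genome(
    transcripts: Mapping[str, CodingTranscript] | Sequence[CodingTranscript],
    variants_by_tx: Mapping[str, Sequence[VariantSite]],
    include_flagged: bool = False,
    **params,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every transcript; return (interval table, per-gene summary).

    Transcripts flagged for internal stop codons are skipped by default.  The
    per-gene summary has one row per gene with ``has_mdr`` and ``n_mdr``.
    """
    if isinstance(transcripts, Mapping):
        txs = list(transcripts.values())
    else:
        txs = list(transcripts)
    if not txs:
        raise ValueError("empty transcript set")
    intervals: list[MDRInterval] = []
    gene_rows: dict[str, dict] = {}
    for tx in txs:
        if tx.has_internal_stop and not include_flagged:
            continue
        ivs = scan_mdr(tx, variants_by_tx.get(tx.transcript_id, ()), **params)
        intervals.extend(ivs)
        row = gene_rows.setdefault(
            tx.gene_symbol, {"gene_symbol": tx.gene_symbol, "n_mdr": 0}
        )
        row["n_mdr"] += len(ivs)
    summary = pd.DataFrame(
        sorted(gene_rows.values(), key=lambda r: r["gene_symbol"]),
        columns=["gene_symbol", "n_mdr"],
    )
    summary["has_mdr"] = summary["n_mdr"] > 0
    return mdr_table(intervals), summary


def mdr_size_sweep(
    transcripts: Mapping[str, CodingTranscript] | Sequence[CodingTranscript],
    variants_by_tx: Mapping[str, Sequence[VariantSite]],
    lengths: Sequence[int],
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> pd.DataFrame:
    """Candidate-region counts under a sweep of minimum-length criteria.

    For each length the synonymous-count requirement scales with the 300 bp /
    10-site ratio: min_syn = max(1, round(length / 30)).  Counts are
    non-increasing in length because the qualifying sets are nested.
    """
    if list(lengths) != sorted(lengths):
        raise ValueError("lengths must be sorted ascending")
    rows = []
    for length in lengths:
        min_syn = max(1, round(length / 30))
        table, _ = scan_genome(
            transcripts,
            variants_by_tx,
            min_length=length,
            min_syn=min_syn,
            density_floor=density_floor,
            project=False,
        )
        rows.append({"min_length": length, "min_syn": min_syn, "n_regions": len(table)})
    return pd.DataFrame(rows)


def variant_density_profile(
    tx: CodingTranscript,
    variants: Sequence[VariantSite],
    var_class: str = MISSENSE,
    window_bp: int = 90,
) -> pd.DataFrame:
    """Sliding-window variant-site density along the CDS, for density plots.

    Windows of ``window_bp`` bases advance one codon (3 bp) at a time; the
    count is the number of distinct variant sites of the class in the window.
    """
    if window_bp < 3:
        raise ValueError("window_bp must be >= 3")
    L = len(tx.cds_seq)
    pos0 = np.asarray(
        sorted({v.cds_pos - 1 for v in variants if v.consequence == var_class}),
        dtype=np.int64,
    )
    starts = np.arange(0, max(L - window_bp, 0) + 1, 3, dtype=np.int64)
    hi = np.searchsorted(pos0, starts + window_bp, side="left")
    lo = np.searchsorted(pos0, starts, side="left")
    return pd.DataFrame(
        {"window_start": starts, "count": (hi - lo).astype(int)}
    )
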