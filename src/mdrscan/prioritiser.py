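"""Rare-variant prioritisation by population missense-depletion evidence.

Proband variants are filtered to rare protein-altering changes, then each
variant-affected gene is placed on two genome-wide rank axes: overall missense
depletion (genic dN/dS, rank 1 = most depleted) and intragenic missense
distribution (EMD, rank 1 = largest shift), with MDR containment and — when
parental genotypes exist — a trio inheritance class as further evidence.
Ranks are computed against the whole scored gene universe, so a proband gene's
rank is its position in the exome-wide distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dnds import GeneConstraint
from .mdr_scan import MDRInterval
from .variant_model import (
    MISSENSE,
    NONSENSE,
    PROTEIN_ALTERING,
    START_LOST,
    STOP_LOST,
    SYNONYMOUS,
    CodingTranscript,
    VariantSite,
)

__all__ = [
    "RankedCandidate",
    "filter_rare_coding",
    "rank_candidates",
    "annotate_trio",
    "report",
    "PAR_REGIONS",
]

PROTEIN_ALTERING_CLASSES = {MISSENSE, NONSENSE, STOP_LOST, START_LOST, PROTEIN_ALTERING}

DE_NOVO = "de_novo"
INHERITED_MATERNAL = "inherited_maternal"
INHERITED_PATERNAL = "inherited_paternal"
COMPOUND_HET = "compound_het"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"
UNKNOWN = "unknown"

_X_NAMES = {"X", "chrX"}
_MT_NAMES = {"MT", "M", "chrM", "chrMT"}

# pseudoautosomal regions (0-based half-open) per reference build
PAR_REGIONS = {
    "GRCh38": ((10_000, 2_781_479), (155_701_382, 156_030_895)),
    "GRCh37": ((60_000, 2_699_520), (154_931_043, 155_260_560)),
}


@dataclass
class RankedCandidate:
    """A proband variant joined to its gene's constraint evidence."""

    variant: VariantSite
    gene_symbol: str
    dnds_value: Optional[float]
    dnds_rank: int  # 1 = most missense-depleted
    emd_value: Optional[float]
    emd_rank: int  # 1 = largest distribution shift
    in_mdr: bool
    inheritance: str = UNKNOWN
    flags: set[str] = field(default_factory=set)

    @property
    def maf(self) -> Optional[float]:
        return self.variant.maf


def filter_rare_coding(
    variants: Iterable[VariantSite], maf_threshold: float = 0.01
) -> list[VariantSite]:
    """Keep protein-altering variants rarer than ``maf_threshold``.

    Synonymous variants are removed; a missing MAF means the allele was not
    observed in the population and is treated as 0 (rare).  Idempotent.
    """
    return [
        v
        for v in variants
        if v.consequence in PROTEIN_ALTERING_CLASSES
        and (v.maf is None or v.maf < maf_threshold)
    ]


def _per_gene_constraints(constraints: Sequence[GeneConstraint]) -> dict[str, GeneConstraint]:
    """One constraint row per gene: the longest CDS wins; ties by transcript id."""
    best: dict[str, GeneConstraint] = {}
    for c in sorted(constraints, key=lambda c: (-c.cds_len, c.transcript_id)):
        best.setdefault(c.gene_symbol, c)
    return best


def _rank_genes(
    per_gene: Mapping[str, GeneConstraint], attr: str, descending: bool
) -> dict[str, int]:
    """Deterministic 1-based ranks over genes; unscored genes rank last.

    Ties break by total observed sites (descending: better-sampled genes
    first) then gene symbol.
    """
    scored = [c for c in per_gene.values() if getattr(c, attr) is not None]
    unscored = [c for c in per_gene.values() if getattr(c, attr) is None]
    sign = -1.0 if descending else 1.0
    scored.sort(
        key=lambda c: (sign * getattr(c, attr), -(c.n_obs + c.s_obs), c.gene_symbol)
    )
    unscored.sort(key=lambda c: c.gene_symbol)
    ranks: dict[str, int] = {}
    for i, c in enumerate(scored + unscored, start=1):
        ranks[c.gene_symbol] = i
    return ranks


def rank_candidates(
    variants: Sequence[VariantSite],
    constraints: Sequence[GeneConstraint],
    mdrs: Sequence[MDRInterval] = (),
    proband_only: bool = False,
) -> list[RankedCandidate]:
    """Join filtered proband variants to genome-wide constraint ranks.

    ``proband_only`` restricts the rank universe to the genes the proband's
    variants fall in (an alternative view; the default ranks against all
    scored genes).  A variant whose gene is absent from the constraint table
    is flagged and ranked after everything else.
    """
    per_gene = _per_gene_constraints(constraints)
    tx_to_gene = {c.transcript_id: c.gene_symbol for c in constraints}
    if proband_only:
        genes = {tx_to_gene.get(v.transcript_id) for v in variants}
        per_gene = {g: c for g, c in per_gene.items() if g in genes}
    dnds_ranks = _rank_genes(per_gene, "dnds", descending=False)
    emd_ranks = _rank_genes(per_gene, "emd", descending=True)
    last = len(per_gene) + 1
    mdr_by_tx: dict[str, list[MDRInterval]] = {}
    for iv in mdrs:
        mdr_by_tx.setdefault(iv.transcript_id, []).append(iv)
    out: list[RankedCandidate] = []
    for v in variants:
        gene = tx_to_gene.get(v.transcript_id)
        c = per_gene.get(gene) if gene is not None else None
        flags: set[str] = set()
        if c is None:
            flags.add("gene_unscored")
            out.append(
                RankedCandidate(
                    variant=v,
                    gene_symbol=gene or v.transcript_id,
                    dnds_value=None,
                    dnds_rank=last,
                    emd_value=None,
                    emd_rank=last,
                    in_mdr=False,
                    flags=flags,
                )
            )
            continue
        flags |= c.flags
        in_mdr = any(
            iv.contains(v.cds_pos) for iv in mdr_by_tx.get(v.transcript_id, ())
        )
        out.append(
            RankedCandidate(
                variant=v,
                gene_symbol=c.gene_symbol,
                dnds_value=c.dnds,
                dnds_rank=dnds_ranks[c.gene_symbol],
                emd_value=c.emd,
                emd_rank=emd_ranks[c.gene_symbol],
                in_mdr=in_mdr,
                flags=flags,
            )
        )
    return out


def _carries(gt: Optional[str]) -> bool:
    return gt in ("het", "hom_alt")


def _in_par(chrom_pos: Optional[int], build: str) -> bool:
    if chrom_pos is None:
        return False
    return any(s <= chrom_pos < e for s, e in PAR_REGIONS[build])


def annotate_trio(
    proband: Sequence[VariantSite],
    mother: Optional[Sequence[VariantSite]],
    father: Optional[Sequence[VariantSite]],
    transcripts: Optional[Mapping[str, CodingTranscript]] = None,
    gene_of: Optional[Mapping[str, str]] = None,
    proband_sex: str = "unknown",
    build: str = "GRCh38",
) -> dict[tuple[str, int, str], str]:
    """Inheritance class per proband variant from parental genotypes.

    With both parent sets supplied, a site absent from a parent's set is taken
    as hom_ref in that parent; with a parent set missing entirely the class is
    unknown.  Classes: de_novo (both parents hom_ref), inherited_maternal /
    inherited_paternal (exactly one carrier parent), homozygous (proband
    hom_alt, not de novo), compound_het (>=2 het variants in one gene with at
    least one inherited from each parent), hemizygous (male proband, X outside
    the pseudoautosomal regions), unknown otherwise.  Annotation never touches
    scores or ranks.
    """
    if mother is None or father is None:
        return {v.key: UNKNOWN for v in proband}
    mgt = {v.key: v.genotype for v in mother}
    fgt = {v.key: v.genotype for v in father}
    gene_of = gene_of or {}
    classes: dict[tuple[str, int, str], str] = {}
    for v in proband:
        tx = transcripts.get(v.transcript_id) if transcripts else None
        chrom = tx.chrom if tx is not None else None
        if chrom in _MT_NAMES:
            classes[v.key] = UNKNOWN
            continue
        if (
            proband_sex == "male"
            and chrom in _X_NAMES
            and _carries(v.genotype)
        ):
            from .variant_model import project_cds_to_genomic

            gpos = project_cds_to_genomic(tx, v.cds_pos)[1] if tx and tx.exon_blocks else None
            if not _in_par(gpos, build):
                classes[v.key] = HEMIZYGOUS
                continue
        m = mgt.get(v.key, "hom_ref")
        f = fgt.get(v.key, "hom_ref")
        if v.genotype is None:
            classes[v.key] = UNKNOWN
        elif not _carries(m) and not _carries(f) and _carries(v.genotype):
            classes[v.key] = DE_NOVO
        elif v.genotype == "hom_alt":
            classes[v.key] = HOMOZYGOUS
        elif _carries(m) and not _carries(f):
            classes[v.key] = INHERITED_MATERNAL
        elif _carries(f) and not _carries(m):
            classes[v.key] = INHERITED_PATERNAL
        else:
            classes[v.key] = UNKNOWN  # carried by both parents: phase ambiguous
    # compound heterozygotes: per gene, >=2 het variants inherited in trans
    by_gene: dict[str, list[VariantSite]] = {}
    for v in proband:
        gene = gene_of.get(v.transcript_id, v.transcript_id)
        by_gene.setdefault(gene, []).append(v)
    for gene, vs in by_gene.items():
        het_inh = [
            v
            for v in vs
            if v.genotype == "het"
            and classes[v.key] in (INHERITED_MATERNAL, INHERITED_PATERNAL)
        ]
        sides = {classes[v.key] for v in het_inh}
        if len(het_inh) >= 2 and sides == {INHERITED_MATERNAL, INHERITED_PATERNAL}:
            for v in het_inh:
                classes[v.key] = COMPOUND_HET
    return classes


def report(
    candidates: Sequence[RankedCandidate],
    out_tsv: Optional[str] = None,
) -> pd.DataFrame:
    """Ranked candidate table, sorted by dN/dS rank (ties: EMD rank, position)."""
    rows = [
        {
            "gene_symbol": c.gene_symbol,
            "transcript_id": c.variant.transcript_id,
            "cds_pos": c.variant.cds_pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "consequence": c.variant.consequence,
            "maf": c.variant.maf,
            "dnds": c.dnds_value,
            "dnds_rank": c.dnds_rank,
            "emd": c.emd_value,
            "emd_rank": c.emd_rank,
            "in_mdr": c.in_mdr,
            "inheritance": c.inheritance,
            "flags": ",".join(sorted(c.flags)),
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "transcript_id",
            "cds_pos",
            "ref",
            "alt",
            "consequence",
            "maf",
            "dnds",
            "dnds_rank",
            "emd",
            "emd_rank",
            "in_mdr",
            "inheritance",
            "flags",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["dnds_rank", "emd_rank", "gene_symbol", "cds_pos"]
        ).reset_index(drop=True)
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df
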