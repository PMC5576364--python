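"""Readers and writers for the standard formats plus run manifests.

Conventions: FASTA record ids are transcript ids, with an optional ``gene=``
tag in the description; exon blocks come from BED12 or GFF3 (CDS features);
VCFs are v4.2, SNV records only for the core statistics.  Synthetic
transcripts without a genomic mapping are written in "CDS space": the VCF
contig is the transcript id and POS is the 1-based CDS position.  Variant
loading is tolerant by design — non-CDS and reference-mismatching records are
counted in a :class:`LoadSummary`, not fatal, because those counts are the
first debugging surface for coordinate problems.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnds import GeneConstraint
from .mdr_scan import MDRInterval
from .variant_model import (
    CodingTranscript,
    NotInCDSError,
    ReferenceMismatchError,
    VariantSite,
    annotate_variant,
    project_genomic_to_cds,
)

logger = logging.getLogger("mdrscan")

__all__ = [
    "read_cds_fasta",
    "write_cds_fasta",
    "read_exon_blocks_bed12",
    "read_exon_blocks_gff3",
    "load_transcripts",
    "load_population_variants",
    "LoadSummary",
    "write_vcf",
    "read_vcf_variants",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_constraints_tsv",
    "read_constraints_tsv",
    "write_mdr_bed",
    "write_mdr_tsv",
    "read_mdr_tsv",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# transcripts


def read_cds_fasta(path: str | Path) -> dict[str, CodingTranscript]:
    """Read CDS sequences; record id = transcript id, optional ``gene=`` tag."""
    out: dict[str, CodingTranscript] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[5:]
        out[rec.id] = CodingTranscript(
            transcript_id=rec.id, gene_symbol=gene, cds_seq=str(rec.seq)
        )
    return out


def write_cds_fasta(path: str | Path, transcripts: Iterable[CodingTranscript]) -> None:
    records = [
        SeqRecord(
            Seq(tx.cds_seq),
            id=tx.transcript_id,
            description=f"gene={tx.gene_symbol}",
        )
        for tx in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_exon_blocks_bed12(
    path: str | Path,
) -> dict[str, tuple[str, list[tuple[str, int, int]], str]]:
    """BED12 -> transcript id -> (chrom, blocks, strand); blocks 0-based half-open."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(chrom, start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out[name] = (chrom, blocks, strand)
    return out


def read_exon_blocks_gff3(
    path: str | Path,
) -> dict[str, tuple[str, list[tuple[str, int, int]], str]]:
    """GFF3 CDS features grouped by Parent (or ID) -> (chrom, blocks, strand)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, tuple[str, list[tuple[str, int, int]], str]] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID") or [feat.id]
        for name in parents:
            chrom, blocks, strand = out.get(name, (feat.seqid, [], feat.strand))
            blocks.append((feat.seqid, feat.start - 1, feat.end))  # GFF3 is 1-based closed
            out[name] = (chrom, blocks, strand)
    return {
        name: (chrom, sorted(blocks, key=lambda b: b[1]), strand)
        for name, (chrom, blocks, strand) in out.items()
    }


def load_transcripts(
    fasta: str | Path, annotation: Optional[str | Path] = None
) -> dict[str, CodingTranscript]:
    """CDS FASTA plus optional BED12/GFF3 exon mapping."""
    txs = read_cds_fasta(fasta)
    if annotation is not None:
        apath = str(annotation)
        if apath.endswith((".gff", ".gff3")):
            mapping = read_exon_blocks_gff3(apath)
        else:
            mapping = read_exon_blocks_bed12(apath)
        for tid, (chrom, blocks, strand) in mapping.items():
            tx = txs.get(tid)
            if tx is None:
                continue
            txs[tid] = CodingTranscript(
                transcript_id=tx.transcript_id,
                gene_symbol=tx.gene_symbol,
                cds_seq=tx.cds_seq,
                exon_blocks=blocks,
                strand=strand,
                is_canonical=tx.is_canonical,
            )
    return txs


# ---------------------------------------------------------------------------
# variants


@dataclass
class LoadSummary:
    """Structured counts from a variant-loading pass."""

    n_read: int = 0
    n_loaded: int = 0
    n_not_snv: int = 0
    n_not_in_cds: int = 0
    n_ref_mismatch: int = 0
    n_unknown_transcript: int = 0
    per_class: dict[str, int] = field(default_factory=dict)

    def count(self, v: VariantSite) -> None:
        self.n_loaded += 1
        self.per_class[v.consequence] = self.per_class.get(v.consequence, 0) + 1


def _chrom_index(
    transcripts: Mapping[str, CodingTranscript],
) -> dict[str, list[CodingTranscript]]:
    idx: dict[str, list[CodingTranscript]] = {}
    for tx in transcripts.values():
        if tx.exon_blocks:
            idx.setdefault(tx.chrom, []).append(tx)
    return idx


def _genotype_from_gt(gt: tuple) -> Optional[str]:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a >= 1 for a in alleles) and len(alleles) > 1:
        return "hom_alt"
    return "het"


def read_vcf_variants(
    path: str | Path,
    transcripts: Mapping[str, CodingTranscript],
    af_key: str = "AF",
    sample_tag: str = "population",
) -> tuple[dict[str, list[VariantSite]], LoadSummary]:
    """Read SNVs from a VCF, projecting genomic records onto transcript CDS.

    VCFs whose contigs are transcript ids are treated as CDS-space (POS is the
    1-based CDS position).  Multi-allelic records decompose into one variant
    per alt allele; non-SNV alleles are skipped and counted.
    """
    import pysam

    summary = LoadSummary()
    out: dict[str, list[VariantSite]] = {t: [] for t in transcripts}
    chrom_idx = _chrom_index(transcripts)
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            afs = rec.info.get(af_key)
            if afs is not None and not isinstance(afs, tuple):
                afs = (afs,)
            genotype = None
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                if gt is not None:
                    genotype = _genotype_from_gt(gt)
            for ai, alt in enumerate(rec.alts or ()):
                summary.n_read += 1
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    summary.n_not_snv += 1
                    continue
                maf = float(afs[ai]) if afs is not None and ai < len(afs) else None
                if rec.chrom in transcripts:  # CDS-space VCF
                    tx = transcripts[rec.chrom]
                    try:
                        v = annotate_variant(
                            tx,
                            rec.pos,
                            alt,
                            expected_ref=rec.ref,
                            maf=maf,
                            sample_tag=sample_tag,
                            genotype=genotype,
                        )
                    except ReferenceMismatchError:
                        summary.n_ref_mismatch += 1
                        continue
                    except ValueError:
                        summary.n_not_in_cds += 1
                        continue
                    out[tx.transcript_id].append(v)
                    summary.count(v)
                    continue
                hits = 0
                for tx in chrom_idx.get(rec.chrom, ()):
                    try:
                        cds_pos, cref, calt = project_genomic_to_cds(
                            tx, rec.chrom, rec.pos - 1, rec.ref, alt
                        )
                    except NotInCDSError:
                        continue
                    try:
                        v = annotate_variant(
                            tx,
                            cds_pos,
                            calt,
                            expected_ref=cref,
                            maf=maf,
                            sample_tag=sample_tag,
                            genotype=genotype,
                        )
                    except ReferenceMismatchError:
                        summary.n_ref_mismatch += 1
                        continue
                    out[tx.transcript_id].append(v)
                    summary.count(v)
                    hits += 1
                if hits == 0:
                    summary.n_not_in_cds += 1
    logger.info(
        "loaded %d/%d variants (%d non-SNV, %d outside CDS, %d ref mismatches): %s",
        summary.n_loaded,
        summary.n_read,
        summary.n_not_snv,
        summary.n_not_in_cds,
        summary.n_ref_mismatch,
        summary.per_class,
    )
    return out, summary


_GT_STRING = {"het": "0/1", "hom_alt": "1/1", "hom_ref": "0/0", None: "./."}


def write_vcf(
    path: str | Path,
    variants: Sequence[VariantSite],
    transcripts: Mapping[str, CodingTranscript],
    sample_name: Optional[str] = None,
    af_key: str = "AF",
) -> None:
    """Write CDS-space VCFv4.2 (contig = transcript id, POS = CDS position).

    Variants are sorted by (transcript, position, alt) so identical inputs
    yield byte-identical files.  A genotype column is emitted when
    ``sample_name`` is given.
    """
    vs = sorted(variants, key=lambda v: (v.transcript_id, v.cds_pos, v.alt))
    tids = sorted({v.transcript_id for v in vs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={af_key},Number=A,Type=Float,Description="Allele frequency">\n')
        if sample_name:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for tid in tids:
            length = len(transcripts[tid].cds_seq) if tid in transcripts else 10**6
            fh.write(f"##contig=<ID={tid},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_name:
            cols += ["FORMAT", sample_name]
        fh.write("\t".join(cols) + "\n")
        for v in vs:
            info = f"{af_key}={v.maf:.6g}" if v.maf is not None else "."
            row = [v.transcript_id, str(v.cds_pos), ".", v.ref, v.alt, ".", "PASS", info]
            if sample_name:
                row += ["GT", _GT_STRING.get(v.genotype, "./.")]
            fh.write("\t".join(row) + "\n")


def write_variants_tsv(path: str | Path, variants: Sequence[VariantSite]) -> None:
    """CDS-space variant table: transcript_id, cds_pos, ref, alt, af."""
    rows = [
        {
            "transcript_id": v.transcript_id,
            "cds_pos": v.cds_pos,
            "ref": v.ref,
            "alt": v.alt,
            "af": v.maf,
        }
        for v in sorted(variants, key=lambda v: (v.transcript_id, v.cds_pos, v.alt))
    ]
    pd.DataFrame(rows, columns=["transcript_id", "cds_pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


def read_variants_tsv(
    path: str | Path,
    transcripts: Mapping[str, CodingTranscript],
    sample_tag: str = "population",
) -> tuple[dict[str, list[VariantSite]], LoadSummary]:
    """Read a CDS-space or genomic 5-column variant table.

    CDS dialect: transcript_id, cds_pos, ref, alt, af.  Genomic dialect:
    chrom, pos (1-based), ref, alt, af — records are projected onto every
    transcript whose CDS covers the position.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    summary = LoadSummary()
    out: dict[str, list[VariantSite]] = {t: [] for t in transcripts}
    cds_space = "transcript_id" in df.columns
    chrom_idx = _chrom_index(transcripts)
    for i, row in enumerate(df.itertuples(index=False), 2):
        summary.n_read += 1
        try:
            maf = None if pd.isna(row.af) else float(row.af)
            if cds_space:
                tx = transcripts.get(row.transcript_id)
                if tx is None:
                    summary.n_unknown_transcript += 1
                    continue
                try:
                    v = annotate_variant(
                        tx, int(row.cds_pos), row.alt, expected_ref=row.ref,
                        maf=maf, sample_tag=sample_tag,
                    )
                except ReferenceMismatchError:
                    summary.n_ref_mismatch += 1
                    continue
                except ValueError:
                    summary.n_not_in_cds += 1
                    continue
                out[tx.transcript_id].append(v)
                summary.count(v)
            else:
                hits = 0
                for tx in chrom_idx.get(str(row.chrom), ()):
                    try:
                        cds_pos, cref, calt = project_genomic_to_cds(
                            tx, str(row.chrom), int(row.pos) - 1, row.ref, row.alt
                        )
                        v = annotate_variant(
                            tx, cds_pos, calt, expected_ref=cref,
                            maf=maf, sample_tag=sample_tag,
                        )
                    except NotInCDSError:
                        continue
                    except ReferenceMismatchError:
                        summary.n_ref_mismatch += 1
                        continue
                    out[tx.transcript_id].append(v)
                    summary.count(v)
                    hits += 1
                if hits == 0:
                    summary.n_not_in_cds += 1
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}:{i}: malformed record ({exc})") from exc
    return out, summary


def load_population_variants(
    path: str | Path,
    transcripts: Mapping[str, CodingTranscript],
    af_key: str = "AF",
) -> tuple[dict[str, list[VariantSite]], LoadSummary]:
    """Dispatch on file type: VCF (.vcf/.vcf.gz) or tabular (.tsv/.txt)."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return read_vcf_variants(path, transcripts, af_key=af_key)
    return read_variants_tsv(path, transcripts)


# ---------------------------------------------------------------------------
# scores / MDR tables


def write_constraints_tsv(path: str | Path, constraints: Sequence[GeneConstraint]) -> None:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "gene_symbol": c.gene_symbol,
            "cds_len": c.cds_len,
            "N_sites": c.N_sites,
            "S_sites": c.S_sites,
            "n_obs": c.n_obs,
            "s_obs": c.s_obs,
            "dnds": c.dnds,
            "emd": c.emd,
            "flags": ",".join(sorted(c.flags)),
        }
        for c in sorted(constraints, key=lambda c: c.transcript_id)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_symbol", "cds_len", "N_sites", "S_sites",
            "n_obs", "s_obs", "dnds", "emd", "flags",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_constraints_tsv(path: str | Path) -> list[GeneConstraint]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GeneConstraint(
                transcript_id=row.transcript_id,
                gene_symbol=row.gene_symbol,
                cds_len=int(row.cds_len),
                N_sites=float(row.N_sites),
                S_sites=float(row.S_sites),
                n_obs=int(row.n_obs),
                s_obs=int(row.s_obs),
                dnds=None if pd.isna(row.dnds) else float(row.dnds),
                emd=None if pd.isna(row.emd) else float(row.emd),
                flags=set() if pd.isna(row.flags) or not row.flags else set(str(row.flags).split(",")),
            )
        )
    return out


def write_mdr_bed(path: str | Path, intervals: Sequence[MDRInterval]) -> None:
    """BED6, one line per genomic block (CDS-space intervals for unmapped
    transcripts use the transcript id as the chromosome)."""
    with open(path, "w") as fh:
        for iv in intervals:
            blocks = iv.genomic_blocks or [
                (iv.transcript_id, iv.cds_start, iv.cds_end)
            ]
            for chrom, s, e in blocks:
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{iv.transcript_id}\t{iv.syn_count}\t+\n"
                )


def write_mdr_tsv(path: str | Path, intervals: Sequence[MDRInterval]) -> None:
    from .mdr_scan import mdr_table

    mdr_table(intervals).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mdr_tsv(path: str | Path) -> list[MDRInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        MDRInterval(
            transcript_id=row.transcript_id,
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            syn_count=int(row.syn_count),
        )
        for row in df.itertuples(index=False)
    ]


def write_manifest(path: str | Path, inputs: dict, parameters: dict, seed: Optional[int]) -> None:
    """JSON run manifest: inputs, parameters, seed and package version."""
    from . import __version__

    manifest = {
        "tool": "mdrscan",
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items() if v is not None},
        "parameters": parameters,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
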