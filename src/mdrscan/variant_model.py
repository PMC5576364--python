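"""Transcript/variant data model, consequence classification and coordinate projection.

Everything downstream (potential-site counting, MDR scanning, EMD scoring,
prioritisation) works in the coordinate frame of a coding sequence (CDS): the
concatenated exonic coding bases of one transcript, 5'->3' in transcript
orientation.  CDS positions are 1-based, matching HGVS "c." notation (c.103T>C
is CDS position 103).  Genomic intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "SYNONYMOUS",
    "MISSENSE",
    "NONSENSE",
    "STOP_LOST",
    "START_LOST",
    "PROTEIN_ALTERING",
    "CODON_TO_AA",
    "CodingTranscript",
    "VariantSite",
    "classify_substitution",
    "annotate_variant",
    "project_genomic_to_cds",
    "project_cds_to_genomic",
    "project_cds_interval_to_genomic",
    "substitution_table",
    "SubstitutionTable",
]

# consequence classes (single-nucleotide substitutions)
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
# opaque class for indels carried through prioritisation only; such variants
# never enter dN/dS, MDR or EMD computations.
PROTEIN_ALTERING = "protein_altering"

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Standard genetic code (NCBI table 1); stops mapped to '*'.
_standard = _CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(codon: str, offset: int, alt: str) -> str:
    """Consequence of substituting ``alt`` at ``offset`` (0..2) of ``codon``.

    Returns one of {synonymous, missense, nonsense, stop_lost}.  A stop codon
    mutating to another stop is synonymous (stop-retained).  ``start_lost`` is
    a caller-level reinterpretation for the initiator codon and is never
    returned here.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASE_INDEX for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if offset not in (0, 1, 2):
        raise ValueError(f"invalid codon offset {offset!r}")
    alt = alt.upper()
    if alt not in _BASE_INDEX:
        raise ValueError(f"invalid alt base {alt!r}")
    if alt == codon[offset]:
        raise ValueError(f"alt base equals reference base {alt!r} in {codon}[{offset}]")
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = CODON_TO_AA[codon]
    aa_alt = CODON_TO_AA[mutated]
    if aa_ref == aa_alt:
        return SYNONYMOUS
    if aa_alt == "*":
        return NONSENSE
    if aa_ref == "*":
        return STOP_LOST
    return MISSENSE


@dataclass
class CodingTranscript:
    """A CDS sequence with an optional genomic exon mapping.

    ``exon_blocks`` are (chrom, start, end) tuples in 0-based half-open genomic
    coordinates, stored in ascending genomic order regardless of strand; on the
    minus strand the CDS runs from the last block backwards, reverse
    complemented.
    """

    transcript_id: str
    gene_symbol: str
    cds_seq: str
    exon_blocks: Optional[Sequence[tuple[str, int, int]]] = None
    strand: str = "+"
    is_canonical: bool = True
    has_internal_stop: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper()
        L = len(self.cds_seq)
        if L == 0 or L % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {L} is not a positive multiple of 3"
            )
        if any(b not in _BASE_INDEX for b in self.cds_seq):
            raise ValueError(f"{self.transcript_id}: CDS contains non-ACGT symbols")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.exon_blocks is not None:
            self.exon_blocks = tuple(
                (str(c), int(s), int(e)) for c, s, e in self.exon_blocks
            )
            total = sum(e - s for _, s, e in self.exon_blocks)
            if total != L:
                raise ValueError(
                    f"{self.transcript_id}: exon blocks span {total} bp but CDS is {L} bp"
                )
        # internal stops are flagged, not fatal: reference dumps contain edge
        # cases; flagged transcripts are excluded from genome-wide scans.
        for i in range(0, L - 3, 3):
            if CODON_TO_AA[self.cds_seq[i : i + 3]] == "*":
                self.has_internal_stop = True
                warnings.warn(
                    f"{self.transcript_id}: internal stop codon at codon {i // 3 + 1}",
                    stacklevel=2,
                )
                break

    def __len__(self) -> int:
        return len(self.cds_seq)

    @property
    def codon_count(self) -> int:
        return len(self.cds_seq) // 3

    @property
    def chrom(self) -> Optional[str]:
        return self.exon_blocks[0][0] if self.exon_blocks else None

    def base_at(self, cds_pos: int) -> str:
        if not 1 <= cds_pos <= len(self.cds_seq):
            raise ValueError(
                f"{self.transcript_id}: CDS position {cds_pos} outside 1..{len(self.cds_seq)}"
            )
        return self.cds_seq[cds_pos - 1]

    def codon_at(self, cds_pos: int) -> tuple[str, int, int]:
        """(codon, codon_index 0-based, offset 0..2) containing ``cds_pos``."""
        idx = (cds_pos - 1) // 3
        offset = (cds_pos - 1) % 3
        return self.cds_seq[3 * idx : 3 * idx + 3], idx, offset


@dataclass
class VariantSite:
    """One single-nucleotide substitution on a transcript CDS."""

    transcript_id: str
    cds_pos: int
    ref: str
    alt: str
    consequence: str
    maf: Optional[float] = None
    sample_tag: str = "population"
    genotype: Optional[str] = None  # het | hom_alt | hom_ref

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.transcript_id, self.cds_pos, self.alt)


class ReferenceMismatchError(ValueError):
    pass


class NotInCDSError(ValueError):
    """Signal that a genomic position does not fall in the transcript CDS."""


def annotate_variant(
    tx: CodingTranscript,
    cds_pos: int,
    alt: str,
    expected_ref: Optional[str] = None,
    maf: Optional[float] = None,
    sample_tag: str = "population",
    genotype: Optional[str] = None,
) -> VariantSite:
    """Build a :class:`VariantSite` with its consequence filled in.

    A substitution in the initiator ATG that changes the encoded residue is
    reported as ``start_lost``.
    """
    ref = tx.base_at(cds_pos)
    alt = alt.upper()
    if expected_ref is not None and expected_ref.upper() != ref:
        raise ReferenceMismatchError(
            f"{tx.transcript_id} c.{cds_pos}: expected ref {expected_ref} but CDS has {ref}"
        )
    if alt == ref:
        raise ValueError(f"{tx.transcript_id} c.{cds_pos}: alt equals ref ({ref})")
    codon, idx, offset = tx.codon_at(cds_pos)
    consequence = classify_substitution(codon, offset, alt)
    if idx == 0 and codon == "ATG" and consequence != SYNONYMOUS:
        consequence = START_LOST
    return VariantSite(
        transcript_id=tx.transcript_id,
        cds_pos=cds_pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        maf=maf,
        sample_tag=sample_tag,
        genotype=genotype,
    )


# ---------------------------------------------------------------------------
# genomic <-> CDS projection


def project_genomic_to_cds(
    tx: CodingTranscript,
    chrom: str,
    gpos: int,
    gref: Optional[str] = None,
    galt: Optional[str] = None,
) -> tuple[int, Optional[str], Optional[str]]:
    """Project a 0-based genomic position onto 1-based CDS coordinates.

    On the minus strand, ref/alt are reverse complemented and positions count
    from the transcript 5' end (the genomically last block).  Raises
    :class:`NotInCDSError` when ``gpos`` falls outside the CDS blocks.
    """
    if tx.exon_blocks is None:
        raise ValueError(f"{tx.transcript_id}: transcript has no genomic exon mapping")
    if chrom != tx.chrom:
        raise ValueError(
            f"{tx.transcript_id}: chromosome mismatch ({chrom} vs {tx.chrom})"
        )
    blocks = tx.exon_blocks
    hit = None
    for i, (_, s, e) in enumerate(blocks):
        if s <= gpos < e:
            hit = i
            break
    if hit is None:
        raise NotInCDSError(f"{tx.transcript_id}: genomic position {gpos} not in CDS")
    if tx.strand == "+":
        before = sum(e - s for _, s, e in blocks[:hit])
        cds_pos = before + (gpos - blocks[hit][1]) + 1
        ref, alt = gref, galt
    else:
        after = sum(e - s for _, s, e in blocks[hit + 1 :])
        cds_pos = after + (blocks[hit][2] - 1 - gpos) + 1
        ref = _COMPLEMENT[gref.upper()] if gref else None
        alt = _COMPLEMENT[galt.upper()] if galt else None
    return cds_pos, ref, alt


def project_cds_to_genomic(tx: CodingTranscript, cds_pos: int) -> tuple[str, int]:
    """Inverse of :func:`project_genomic_to_cds` for a single position."""
    if tx.exon_blocks is None:
        raise ValueError(f"{tx.transcript_id}: transcript has no genomic exon mapping")
    if not 1 <= cds_pos <= len(tx.cds_seq):
        raise ValueError(f"{tx.transcript_id}: CDS position {cds_pos} out of range")
    offset = cds_pos - 1  # 0-based along CDS
    blocks = tx.exon_blocks if tx.strand == "+" else tuple(reversed(tx.exon_blocks))
    for chrom, s, e in blocks:
        blen = e - s
        if offset < blen:
            if tx.strand == "+":
                return chrom, s + offset
            return chrom, e - 1 - offset
        offset -= blen
    raise AssertionError("unreachable: exon blocks shorter than CDS")


def project_cds_interval_to_genomic(
    tx: CodingTranscript, cds_start: int, cds_end: int
) -> list[tuple[str, int, int]]:
    """Project a 0-based half-open CDS interval to genomic blocks.

    Returns blocks in ascending genomic order; an interval spanning an intron
    is split across blocks.
    """
    out: list[tuple[str, int, int]] = []
    for p0 in range(cds_start, cds_end):
        chrom, g = project_cds_to_genomic(tx, p0 + 1)
        if out and out[-1][0] == chrom and out[-1][2] == g:
            out[-1] = (chrom, out[-1][1], g + 1)
        elif out and out[-1][0] == chrom and out[-1][1] == g + 1:
            out[-1] = (chrom, g, out[-1][2])
        else:
            out.append((chrom, g, g + 1))
    return sorted(out, key=lambda b: (b[0], b[1]))


# ---------------------------------------------------------------------------
# vectorised substitution enumeration (shared by dnds + synthetic modules)

_CLS_CODE = {SYNONYMOUS: 0, MISSENSE: 1, NONSENSE: 2, STOP_LOST: 3}
CLS_SYN, CLS_MIS, CLS_NON, CLS_STOPLOST = 0, 1, 2, 3

_BYTE_TO_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BYTE_TO_CODE[ord(_b)] = _i


def seq_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes 0..3."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    aa64 = np.empty(64, dtype="<U1")
    cls = np.zeros((64, 3, 3), dtype=np.int8)
    altb = np.zeros((64, 3, 3), dtype=np.int8)
    for ci in range(64):
        codon = BASES[ci >> 4] + BASES[(ci >> 2) & 3] + BASES[ci & 3]
        aa64[ci] = CODON_TO_AA[codon]
        for off in range(3):
            alts = [b for b in range(4) if b != _BASE_INDEX[codon[off]]]
            for k, a in enumerate(alts):
                altb[ci, off, k] = a
                cls[ci, off, k] = _CLS_CODE[
                    classify_substitution(codon, off, BASES[a])
                ]
    is_stop = aa64 == "*"
    return aa64, cls, altb, is_stop


AA64, CLS_TABLE, ALT_TABLE, IS_STOP64 = _build_tables()


@dataclass(frozen=True)
class SubstitutionTable:
    """All possible single-base substitutions of a CDS, excluding the stop codon.

    Parallel flat arrays of length 9 x (codon_count - 1): 1-based CDS position,
    alternative base code (0..3) and consequence class code.
    """

    transcript_id: str
    cds_pos: np.ndarray  # int32, 1-based
    alt_code: np.ndarray  # int8
    cls_code: np.ndarray  # int8


def codon_indices(tx: CodingTranscript) -> np.ndarray:
    codes = seq_codes(tx.cds_seq)
    return (codes[0::3].astype(np.int32) << 4) | (codes[1::3].astype(np.int32) << 2) | codes[2::3]


_SUBS_CACHE: dict[tuple[str, str], SubstitutionTable] = {}


def substitution_table(tx: CodingTranscript) -> SubstitutionTable:
    """Enumerate every (position, alt) substitution of ``tx`` with its class.

    The terminal stop codon is excluded (it contributes no potential N/S sites);
    internal stop codons of flagged transcripts are retained and classified
    relative to the stop (stop-retained changes are synonymous).
    """
    key = (tx.transcript_id, tx.cds_seq[:64] + str(len(tx.cds_seq)))
    cached = _SUBS_CACHE.get(key)
    if cached is not None:
        return cached
    cod = codon_indices(tx)[:-1]  # drop terminal stop codon
    n = cod.size
    cls = CLS_TABLE[cod]  # (n, 3, 3)
    alt = ALT_TABLE[cod]
    pos = (
        (np.arange(n, dtype=np.int32)[:, None, None] * 3)
        + np.arange(3, dtype=np.int32)[None, :, None]
        + 1
    )
    pos = np.broadcast_to(pos, (n, 3, 3))
    table = SubstitutionTable(
        transcript_id=tx.transcript_id,
        cds_pos=np.ascontiguousarray(pos.reshape(-1)),
        alt_code=np.ascontiguousarray(alt.reshape(-1)),
        cls_code=np.ascontiguousarray(cls.reshape(-1)),
    )
    if len(_SUBS_CACHE) > 4096:
        _SUBS_CACHE.clear()
    _SUBS_CACHE[key] = table
    return table
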