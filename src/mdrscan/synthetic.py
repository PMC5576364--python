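"""Synthetic transcripts, population variant sets and trios with known truth.

The stochastic generator places each possible substitution (position, alt)
independently with probability lambda_class / 3, so the expected number of
variants of a class equals lambda_class times the class's potential site count
— the rare-variant regime in which recurrence and linkage are negligible.
Missense-free regions are planted by multiplying the missense (and nonsense)
placement probability inside an interval by ``epsilon`` (default 0, fully
depleted).  Allele frequencies follow a rare spectrum, log-uniform on
[1e-5, 5e-3], mimicking the site-frequency shape of large exome cohorts; they
are decorative for the site-based statistics but exercised by the MAF filter.

Two structured placement fixtures complement the Bernoulli model for scanner
calibration, where near-deterministic densities are wanted:
``regular_synonymous_sites`` (one synonymous site per spacing-bp grid point)
and ``blockwise_missense_sites`` (one missense site uniformly placed per
block, so the density is exact and the maximum gap is below two blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .variant_model import (
    BASES,
    CLS_MIS,
    CLS_NON,
    CLS_SYN,
    MISSENSE,
    NONSENSE,
    STOP_LOST,
    SYNONYMOUS,
    CodingTranscript,
    VariantSite,
    substitution_table,
)

__all__ = [
    "SimulationConfig",
    "TrioSpec",
    "TrioResult",
    "make_transcript",
    "simulate_population_variants",
    "regular_synonymous_sites",
    "blockwise_missense_sites",
    "simulate_exome",
    "simulate_trio",
    "rare_maf",
]

_CLS_NAME = {CLS_SYN: SYNONYMOUS, CLS_MIS: MISSENSE, CLS_NON: NONSENSE, 3: STOP_LOST}

# sense codons (indices into the 64-codon table), fixed order for reproducibility
from .variant_model import IS_STOP64

_SENSE_CODONS = [i for i in range(64) if not IS_STOP64[i]]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


def _codon_str(ci: int) -> str:
    return BASES[ci >> 4] + BASES[(ci >> 2) & 3] + BASES[ci & 3]


@dataclass
class TrioSpec:
    """Trio simulation: background inherited variants plus one de novo causal.

    ``n_background`` rare protein-altering variants are given to the proband,
    each inherited (het) from one random parent; the causal missense is placed
    inside the planted interval of ``causal_transcript`` and is absent from
    both parents.  Decoy synonymous and common (MAF >= 2%) protein-altering
    proband variants exercise the rare-coding filter without surviving it.
    """

    causal_transcript: str
    n_background: int = 480
    n_synonymous_decoys: int = 120
    n_common_decoys: int = 40


@dataclass
class SimulationConfig:
    """Reproducible study configuration; ``seed`` drives every random choice.

    ``lambda_s``/``lambda_m`` are expected variants per potential synonymous /
    nonsynonymous site; ``planted_mdrs`` maps transcript index -> 0-based
    half-open CDS interval whose missense rate is multiplied by ``epsilon``.
    """

    seed: int
    n_transcripts: int = 100
    cds_length_range: tuple[int, int] = (900, 3000)
    lambda_s: float = 0.2
    lambda_m: float = 0.2
    planted_mdrs: Mapping[int, tuple[int, int]] = field(default_factory=dict)
    epsilon: float = 0.0
    trio: Optional[TrioSpec] = None

    def __post_init__(self) -> None:
        for lam in (self.lambda_s, self.lambda_m):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"rate {lam} outside [0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon {self.epsilon} outside [0, 1]")


def rare_maf(rng: np.random.Generator, n: int) -> np.ndarray:
    """Rare-spectrum allele frequencies, log-uniform on [1e-5, 5e-3]."""
    return np.exp(rng.uniform(np.log(1e-5), np.log(5e-3), size=n))


def make_transcript(
    length_bp: int,
    seed: int | np.random.Generator,
    transcript_id: str = "TX1",
    gene_symbol: Optional[str] = None,
) -> CodingTranscript:
    """Random CDS: ATG start, random sense codons, one terminal stop."""
    if length_bp % 3 != 0 or length_bp < 60:
        raise ValueError(f"length must be a multiple of 3 and >= 60, got {length_bp}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_codons = length_bp // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    seq = "ATG" + "".join(_codon_str(int(c)) for c in body) + _STOP_CODONS[
        int(rng.integers(3))
    ]
    return CodingTranscript(
        transcript_id=transcript_id,
        gene_symbol=gene_symbol or transcript_id,
        cds_seq=seq,
    )


def simulate_population_variants(
    tx: CodingTranscript,
    lambda_m: float,
    lambda_s: float,
    rng: np.random.Generator,
    planted_interval: Optional[tuple[int, int]] = None,
    epsilon: float = 0.0,
) -> list[VariantSite]:
    """Independent per-(position, alt) Bernoulli placement of population variants.

    Synonymous-creating alts appear with probability lambda_s / 3; missense-
    and nonsense-creating alts with lambda_m / 3 (nonsense is placed like
    missense but labelled by its true consequence, keeping classifiers honest).
    Inside ``planted_interval`` (0-based half-open CDS) the missense/nonsense
    probability is multiplied by ``epsilon``.
    """
    for lam in (lambda_m, lambda_s):
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"rate {lam} outside [0, 1]")
    tab = substitution_table(tx)
    p = np.where(tab.cls_code == CLS_SYN, lambda_s / 3.0, lambda_m / 3.0)
    if planted_interval is not None:
        s, e = planted_interval
        if not (0 <= s < e <= len(tx.cds_seq)):
            raise ValueError(f"planted interval {planted_interval} outside CDS")
        in_planted = (tab.cds_pos - 1 >= s) & (tab.cds_pos - 1 < e)
        p = np.where(in_planted & (tab.cls_code != CLS_SYN), p * epsilon, p)
    sel = np.flatnonzero(rng.random(p.size) < p)
    mafs = rare_maf(rng, sel.size)
    seq = tx.cds_seq
    return [
        VariantSite(
            transcript_id=tx.transcript_id,
            cds_pos=int(tab.cds_pos[i]),
            ref=seq[int(tab.cds_pos[i]) - 1],
            alt=BASES[int(tab.alt_code[i])],
            consequence=_CLS_NAME[int(tab.cls_code[i])],
            maf=float(m),
            sample_tag="population",
        )
        for i, m in zip(sel, mafs)
    ]


def _class_slots(tx: CodingTranscript, cls: int) -> tuple[np.ndarray, np.ndarray]:
    tab = substitution_table(tx)
    idx = np.flatnonzero(tab.cls_code == cls)
    return tab.cds_pos[idx], tab.alt_code[idx]


def regular_synonymous_sites(
    tx: CodingTranscript,
    spacing: int,
    rng: Optional[np.random.Generator] = None,
) -> list[VariantSite]:
    """One synonymous site per ``spacing``-bp grid point (calibration fixture).

    For each grid point the nearest CDS position offering a synonymous alt is
    used, giving a near-deterministic density of 1/spacing per bp.
    """
    pos, alt = _class_slots(tx, CLS_SYN)
    uniq_pos, first_idx = np.unique(pos, return_index=True)
    out: list[VariantSite] = []
    used: set[int] = set()
    rng = rng or np.random.default_rng(0)
    mafs = rare_maf(rng, max(1, len(tx.cds_seq) // spacing + 1))
    k = 0
    for grid in range(spacing // 2, len(tx.cds_seq) - 2, spacing):
        j = int(np.argmin(np.abs(uniq_pos - (grid + 1))))
        p = int(uniq_pos[j])
        if p in used:
            continue
        used.add(p)
        i = int(first_idx[j])
        out.append(
            VariantSite(
                transcript_id=tx.transcript_id,
                cds_pos=p,
                ref=tx.cds_seq[p - 1],
                alt=BASES[int(alt[i])],
                consequence=SYNONYMOUS,
                maf=float(mafs[min(k, mafs.size - 1)]),
                sample_tag="population",
            )
        )
        k += 1
    return out


def blockwise_missense_sites(
    tx: CodingTranscript,
    block_bp: int,
    rng: np.random.Generator,
    exclude_interval: Optional[tuple[int, int]] = None,
) -> list[VariantSite]:
    """One missense site uniformly placed per consecutive ``block_bp`` block.

    Produces an exact density of 1/block_bp per bp with maximum gap below
    2 x block_bp — a calibration fixture for false-positive studies where the
    gap distribution must stay well below the MDR length criterion.
    """
    pos, alt = _class_slots(tx, CLS_MIS)
    out: list[VariantSite] = []
    L = len(tx.cds_seq)
    mafs = rare_maf(rng, L // block_bp + 1)
    k = 0
    for start in range(0, L - block_bp + 1, block_bp):
        if exclude_interval is not None:
            s, e = exclude_interval
            if start < e and start + block_bp > s:
                continue
        in_block = np.flatnonzero((pos > start) & (pos <= start + block_bp))
        if in_block.size == 0:
            continue
        i = int(rng.choice(in_block))
        out.append(
            VariantSite(
                transcript_id=tx.transcript_id,
                cds_pos=int(pos[i]),
                ref=tx.cds_seq[int(pos[i]) - 1],
                alt=BASES[int(alt[i])],
                consequence=MISSENSE,
                maf=float(mafs[k]),
                sample_tag="population",
            )
        )
        k += 1
    return out


@dataclass
class ExomeSim:
    transcripts: dict[str, CodingTranscript]
    variants_by_tx: dict[str, list[VariantSite]]
    planted: dict[str, tuple[int, int]]  # transcript_id -> planted CDS interval


def simulate_exome(config: SimulationConfig) -> ExomeSim:
    """Simulate a transcript set with population variants per the config."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    transcripts: dict[str, CodingTranscript] = {}
    variants: dict[str, list[VariantSite]] = {}
    planted: dict[str, tuple[int, int]] = {}
    for i in range(config.n_transcripts):
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        tid = f"SYNTX{i:04d}"
        tx = make_transcript(length, rng, transcript_id=tid, gene_symbol=f"SYNG{i:04d}")
        interval = config.planted_mdrs.get(i)
        if interval is not None:
            s, e = interval
            e = min(e, length)
            interval = (s, e)
            planted[tid] = interval
        transcripts[tid] = tx
        variants[tid] = simulate_population_variants(
            tx,
            config.lambda_m,
            config.lambda_s,
            rng,
            planted_interval=interval,
            epsilon=config.epsilon,
        )
    return ExomeSim(transcripts, variants, planted)


@dataclass
class TrioResult:
    proband: list[VariantSite]
    mother: list[VariantSite]
    father: list[VariantSite]
    truth: dict


def simulate_trio(
    transcripts: Mapping[str, CodingTranscript],
    config: SimulationConfig,
    planted: Optional[Mapping[str, tuple[int, int]]] = None,
) -> TrioResult:
    """Simulate proband/mother/father variant sets with a planted causal de novo.

    Background protein-altering variants are sampled without replacement from
    the non-causal transcripts' missense/nonsense substitution slots; each is
    het in the proband and het in exactly one parent.  The causal missense is
    het in the proband, absent from both parents, and lies inside the causal
    transcript's planted interval.
    """
    if config.trio is None:
        raise ValueError("config.trio must be set")
    spec = config.trio
    planted = planted or {}
    if spec.causal_transcript not in transcripts:
        raise ValueError(f"causal transcript {spec.causal_transcript} not in set")
    if spec.causal_transcript not in planted:
        raise ValueError(
            f"causal transcript {spec.causal_transcript} has no planted interval"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    tids = sorted(t for t in transcripts if t != spec.causal_transcript)

    def _sample_slots(cls_codes: tuple[int, ...], count: int) -> list[tuple[str, int, int]]:
        # (transcript, pos, alt_code) slots of the wanted classes, spread over genes
        chosen: list[tuple[str, int, int]] = []
        picked_tids = rng.choice(tids, size=count, replace=len(tids) < count)
        for tid in picked_tids:
            tab = substitution_table(transcripts[tid])
            idx = np.flatnonzero(np.isin(tab.cls_code, cls_codes))
            i = int(rng.choice(idx))
            chosen.append((tid, int(tab.cds_pos[i]), int(tab.alt_code[i])))
        return chosen

    proband: list[VariantSite] = []
    mother: list[VariantSite] = []
    father: list[VariantSite] = []

    def _mk(tid: str, pos: int, altc: int, maf, tag: str, gt: str) -> VariantSite:
        tx = transcripts[tid]
        tab = substitution_table(tx)
        i = int(
            np.flatnonzero((tab.cds_pos == pos) & (tab.alt_code == altc))[0]
        )
        return VariantSite(
            transcript_id=tid,
            cds_pos=pos,
            ref=tx.cds_seq[pos - 1],
            alt=BASES[altc],
            consequence=_CLS_NAME[int(tab.cls_code[i])],
            maf=maf,
            sample_tag=tag,
            genotype=gt,
        )

    seen: set[tuple[str, int, int]] = set()
    background = []
    for slot in _sample_slots((CLS_MIS, CLS_NON), spec.n_background * 2):
        if slot not in seen:
            seen.add(slot)
            background.append(slot)
        if len(background) == spec.n_background:
            break
    assert len(background) == spec.n_background
    mafs = rare_maf(rng, spec.n_background)
    truth_bg = []
    for (tid, pos, altc), maf in zip(background, mafs):
        parent = "mother" if rng.random() < 0.5 else "father"
        proband.append(_mk(tid, pos, altc, float(maf), "proband", "het"))
        carrier = mother if parent == "mother" else father
        carrier.append(_mk(tid, pos, altc, float(maf), parent, "het"))
        truth_bg.append({"transcript_id": tid, "cds_pos": pos, "from": parent})

    # decoys: synonymous (filtered for consequence) and common (filtered for MAF)
    for tid, pos, altc in {
        s: None for s in _sample_slots((CLS_SYN,), spec.n_synonymous_decoys)
    }:
        if (tid, pos, altc) in seen:
            continue
        seen.add((tid, pos, altc))
        proband.append(_mk(tid, pos, altc, float(rare_maf(rng, 1)[0]), "proband", "het"))
    for tid, pos, altc in _sample_slots((CLS_MIS,), spec.n_common_decoys):
        if (tid, pos, altc) in seen:
            continue
        seen.add((tid, pos, altc))
        maf = float(rng.uniform(0.02, 0.2))
        proband.append(_mk(tid, pos, altc, maf, "proband", "het"))
        mother.append(_mk(tid, pos, altc, maf, "mother", "het"))

    # causal de novo missense inside the planted interval
    ctx = transcripts[spec.causal_transcript]
    s, e = planted[spec.causal_transcript]
    tab = substitution_table(ctx)
    in_mdr = np.flatnonzero(
        (tab.cls_code == CLS_MIS) & (tab.cds_pos - 1 >= s) & (tab.cds_pos - 1 < e)
    )
    if in_mdr.size == 0:
        raise ValueError("planted interval offers no missense substitution")
    i = int(rng.choice(in_mdr))
    causal = _mk(
        spec.causal_transcript,
        int(tab.cds_pos[i]),
        int(tab.alt_code[i]),
        None,
        "proband",
        "het",
    )
    proband.append(causal)

    truth = {
        "causal": {
            "transcript_id": causal.transcript_id,
            "cds_pos": causal.cds_pos,
            "ref": causal.ref,
            "alt": causal.alt,
            "inheritance": "de_novo",
        },
        "background": truth_bg,
    }
    return TrioResult(proband=proband, mother=mother, father=father, truth=truth)
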