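import numpy as np
import pytest

from mdrscan.variant_model import CodingTranscript, VariantSite


@pytest.fixture
def toy_tx() -> CodingTranscript:
    # Met-Tyr-stop: the smallest CDS exercising start, body and stop codons
    return CodingTranscript("TOY1", "TOYG", "ATGTATTAA")


@pytest.fixture
def multiexon_plus() -> CodingTranscript:
    # 9 bp CDS split 4+5 across an intron on the plus strand
    return CodingTranscript(
        "MEP", "MEPG", "ATGTATTAA",
        exon_blocks=[("chr1", 100, 104), ("chr1", 200, 205)], strand="+",
    )


@pytest.fixture
def multiexon_minus() -> CodingTranscript:
    # same CDS on the minus strand: genomic sequence is the reverse complement,
    # CDS starts in the genomically last block
    return CodingTranscript(
        "MEM", "MEMG", "ATGTATTAA",
        exon_blocks=[("chr2", 100, 105), ("chr2", 200, 204)], strand="-",
    )


def mk_variant(tx, cds_pos, consequence, alt="N", maf=1e-4, **kw) -> VariantSite:
    """Hand-built variant for tests that only need position + consequence."""
    return VariantSite(
        transcript_id=tx.transcript_id,
        cds_pos=cds_pos,
        ref=tx.cds_seq[cds_pos - 1],
        alt=alt,
        consequence=consequence,
        maf=maf,
        **kw,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
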