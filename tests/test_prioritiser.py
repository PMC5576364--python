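"""Rare-coding filter, rank joins, trio inheritance annotation."""

import numpy as np
import pytest

from conftest import mk_variant
from mdrscan.dnds import GeneConstraint
from mdrscan.mdr_scan import MDRInterval
from mdrscan.prioritiser import (
    annotate_trio,
    filter_rare_coding,
    rank_candidates,
    report,
)
from mdrscan.synthetic import make_transcript
from mdrscan.variant_model import (
    MISSENSE,
    NONSENSE,
    PROTEIN_ALTERING,
    SYNONYMOUS,
    CodingTranscript,
    VariantSite,
)


def _v(tx_id, pos, cons, maf=1e-4, gt="het"):
    return VariantSite(tx_id, pos, "A", "G", cons, maf=maf,
                       sample_tag="proband", genotype=gt)


class TestFilterRareCoding:
    def test_consequence_and_maf_filters(self):
        vs = [
            _v("T1", 10, MISSENSE, maf=0.005),
            _v("T1", 20, SYNONYMOUS, maf=0.005),
            _v("T1", 30, MISSENSE, maf=0.02),
        ]
        kept = filter_rare_coding(vs)
        assert [v.cds_pos for v in kept] == [10]

    def test_absent_maf_means_unobserved_hence_rare(self):
        assert filter_rare_coding([_v("T1", 10, MISSENSE, maf=None)])

    def test_indels_pass_as_opaque_protein_altering(self):
        assert filter_rare_coding([_v("T1", 10, PROTEIN_ALTERING)])

    def test_empty_and_idempotent(self):
        assert filter_rare_coding([]) == []
        vs = [_v("T1", p, MISSENSE, maf=m) for p, m in ((1, 0.001), (2, 0.5))]
        once = filter_rare_coding(vs)
        assert filter_rare_coding(once) == once


def _constraint(tid, gene, dnds, emd, n=10, s=10, cds_len=900):
    return GeneConstraint(tid, gene, cds_len, 600.0, 300.0, n, s, dnds=dnds, emd=emd)


class TestRankCandidates:
    def _table(self):
        return [
            _constraint("T1", "G1", 0.1, 0.30),
            _constraint("T2", "G2", 0.5, 0.10),
            _constraint("T3", "G3", 0.9, 0.05),
            _constraint("T4", "G4", None, None),  # unscored, must sort last
        ]

    def test_rank_axes_and_mdr_containment(self):
        variants = [_v("T2", 50, MISSENSE), _v("T1", 120, MISSENSE)]
        mdrs = [MDRInterval("T1", 100, 500, syn_count=15)]
        cands = rank_candidates(variants, self._table(), mdrs)
        by_gene = {c.gene_symbol: c for c in cands}
        assert by_gene["G1"].dnds_rank == 1 and by_gene["G1"].emd_rank == 1
        assert by_gene["G2"].dnds_rank == 2 and by_gene["G2"].emd_rank == 2
        assert by_gene["G1"].in_mdr and not by_gene["G2"].in_mdr

    def test_ranks_are_a_permutation_over_genes(self):
        table = self._table()
        variants = [_v(f"T{i}", 10, MISSENSE) for i in (1, 2, 3, 4)]
        cands = rank_candidates(variants, table)
        assert sorted(c.dnds_rank for c in cands) == [1, 2, 3, 4]
        assert cands[3].dnds_rank == 4  # unscored gene G4 last
        assert "low_synonymous" not in cands[0].flags

    def test_tie_break_by_observed_sites_then_symbol(self):
        table = [
            _constraint("TA", "GA", 0.5, 0.1, n=3, s=3),
            _constraint("TB", "GB", 0.5, 0.1, n=10, s=10),
        ]
        cands = rank_candidates([_v("TA", 1, MISSENSE), _v("TB", 1, MISSENSE)], table)
        by_gene = {c.gene_symbol: c.dnds_rank for c in cands}
        assert by_gene == {"GB": 1, "GA": 2}  # better-sampled gene first

    def test_unknown_gene_flagged_and_ranked_last(self):
        cands = rank_candidates([_v("TX", 1, MISSENSE)], self._table())
        assert cands[0].dnds_rank == 5
        assert "gene_unscored" in cands[0].flags

    def test_longest_cds_represents_the_gene(self):
        table = [
            _constraint("T1a", "G1", 0.9, 0.1, cds_len=300),
            _constraint("T1b", "G1", 0.1, 0.3, cds_len=1500),
            _constraint("T2", "G2", 0.5, 0.2),
        ]
        cands = rank_candidates([_v("T1a", 5, MISSENSE)], table)
        assert cands[0].dnds_value == 0.1  # longest transcript's score


class TestAnnotateTrio:
    def test_de_novo_when_parents_hom_ref(self):
        proband = [_v("T1", 10, MISSENSE)]
        classes = annotate_trio(proband, [], [])
        assert classes[proband[0].key] == "de_novo"

    def test_missing_parent_set_gives_unknown(self):
        proband = [_v("T1", 10, MISSENSE)]
        assert annotate_trio(proband, None, []) == {proband[0].key: "unknown"}

    def test_inherited_sides(self):
        a, b = _v("T1", 10, MISSENSE), _v("T1", 20, MISSENSE)
        classes = annotate_trio([a, b], [a], [b], gene_of={})
        # trans pair in one gene -> compound het on both
        assert classes[a.key] == "compound_het"
        assert classes[b.key] == "compound_het"

    def test_cis_by_parent_is_not_compound_het(self):
        a, b = _v("T1", 10, MISSENSE), _v("T1", 20, MISSENSE)
        classes = annotate_trio([a, b], [a, b], [])
        assert classes[a.key] == "inherited_maternal"
        assert classes[b.key] == "inherited_maternal"

    def test_compound_het_requires_same_gene(self):
        a, b = _v("T1", 10, MISSENSE), _v("T2", 20, MISSENSE)
        classes = annotate_trio([a, b], [a], [b], gene_of={"T1": "G1", "T2": "G2"})
        assert classes[a.key] == "inherited_maternal"
        assert classes[b.key] == "inherited_paternal"

    def test_hom_alt_is_homozygous(self):
        v = _v("T1", 10, MISSENSE, gt="hom_alt")
        carrier = _v("T1", 10, MISSENSE)
        assert annotate_trio([v], [carrier], [carrier])[v.key] == "homozygous"

    def test_both_parent_carriers_het_is_phase_ambiguous(self):
        v = _v("T1", 10, MISSENSE)
        assert annotate_trio([v], [v], [v])[v.key] == "unknown"

    def test_male_x_variant_is_hemizygous_outside_par(self):
        tx = CodingTranscript(
            "TX", "GX", "ATGTATTAA",
            exon_blocks=[("chrX", 5_000_000, 5_000_009)], strand="+",
        )
        v = _v("TX", 4, MISSENSE)
        classes = annotate_trio([v], [], [], transcripts={"TX": tx},
                                proband_sex="male")
        assert classes[v.key] == "hemizygous"
        # female proband: ordinary autosomal-style logic applies
        classes = annotate_trio([v], [], [], transcripts={"TX": tx},
                                proband_sex="female")
        assert classes[v.key] == "de_novo"

    def test_mitochondrial_passes_through_unknown(self):
        tx = CodingTranscript(
            "TM", "GM", "ATGTATTAA",
            exon_blocks=[("chrM", 100, 109)], strand="+",
        )
        v = _v("TM", 4, MISSENSE)
        assert annotate_trio([v], [], [], transcripts={"TM": tx})[v.key] == "unknown"


class TestReport:
    def test_empty_candidates_give_empty_report(self, tmp_path):
        out = tmp_path / "r.tsv"
        df = report([], out_tsv=str(out))
        assert len(df) == 0 and out.exists()

    def test_rows_sorted_by_depletion_rank(self):
        table = [
            _constraint("T1", "G1", 0.1, 0.3),
            _constraint("T2", "G2", 0.5, 0.1),
        ]
        cands = rank_candidates([_v("T2", 9, MISSENSE), _v("T1", 5, MISSENSE)], table)
        df = report(cands)
        assert list(df["gene_symbol"]) == ["G1", "G2"]
        assert len(df) == 2


def test_trio_annotation_never_changes_ranks(rng):
    """Adding parental data fills the inheritance column only."""
    from mdrscan.pipeline import prioritise
    from mdrscan.studies import _trio_universe
    from mdrscan.synthetic import SimulationConfig, TrioSpec, simulate_trio
    from mdrscan.pipeline import score_transcripts
    from mdrscan.synthetic import simulate_population_variants

    transcripts, causal_id, planted = _trio_universe(7, n_genes=40)
    variants = {
        tid: simulate_population_variants(tx, 0.15, 0.2, rng)
        for tid, tx in transcripts.items()
    }
    constraints, mdrs = score_transcripts(transcripts, variants, scan=True, project=False)
    config = SimulationConfig(
        seed=7, trio=TrioSpec(causal_transcript=causal_id, n_background=60)
    )
    trio = simulate_trio(transcripts, config, planted=planted)
    with_parents = prioritise(trio.proband, constraints, mdrs,
                              mother=trio.mother, father=trio.father,
                              transcripts=transcripts)
    solo = prioritise(trio.proband, constraints, mdrs)
    assert len(with_parents) == len(solo) == 61  # background + causal
    for a, b in zip(with_parents, solo):
        assert (a.dnds_rank, a.emd_rank, a.in_mdr) == (b.dnds_rank, b.emd_rank, b.in_mdr)
    assert any(c.inheritance == "de_novo" for c in with_parents)
    assert all(c.inheritance == "unknown" for c in solo)
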