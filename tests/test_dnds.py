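"""Potential-site counting and genic dN/dS."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import mk_variant
from mdrscan.dnds import (
    codon_potential_sites,
    compare_gene_sets,
    genic_dnds,
    transcript_potential_sites,
)
from mdrscan.synthetic import make_transcript, simulate_population_variants
from mdrscan.variant_model import (
    BASES,
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    CodingTranscript,
)

SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def _oracle_sites(codon: str) -> tuple[float, float]:
    """Brute-force N/S via direct translation of all 9 single-base changes."""
    n = s = 0.0
    for off in range(3):
        syn = 0
        for alt in BASES:
            if alt == codon[off]:
                continue
            mutated = codon[:off] + alt + codon[off + 1 :]
            if str(Seq(codon).translate()) == str(Seq(mutated).translate()):
                syn += 1
        s += syn / 3.0
        n += 1.0 - syn / 3.0
    return n, s


class TestPotentialSites:
    def test_examples(self):
        assert codon_potential_sites("TTT") == pytest.approx((8 / 3, 1 / 3))
        assert codon_potential_sites("ATG") == pytest.approx((3.0, 0.0))

    def test_all_sense_codons_match_enumeration_oracle_and_partition(self):
        total = 0.0
        for codon in SENSE_CODONS:
            n, s = codon_potential_sites(codon)
            assert (n, s) == pytest.approx(_oracle_sites(codon), abs=1e-12)
            assert n + s == pytest.approx(3.0, abs=1e-9)
            total += n + s
        assert len(SENSE_CODONS) == 61
        assert total == pytest.approx(183.0, abs=1e-9)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_potential_sites("TAA")

    def test_transcript_sums_codons_excluding_terminal_stop(self):
        tx = CodingTranscript("T", "T", "ATGTTTTAA")
        assert transcript_potential_sites(tx) == pytest.approx((3 + 8 / 3, 1 / 3))
        tx2 = CodingTranscript("T", "T", "ATG" * 25 + "TAA")
        assert transcript_potential_sites(tx2) == pytest.approx((75.0, 0.0))

    def test_transcript_partition_invariant(self, rng):
        for _ in range(5):
            tx = make_transcript(3 * int(rng.integers(20, 200)), rng)
            n, s = transcript_potential_sites(tx)
            assert n + s == pytest.approx(3 * (tx.codon_count - 1), abs=1e-9)


class TestGenicDnds:
    def test_ratio_formula(self, rng):
        tx = make_transcript(600, rng, "T1")
        N, S = transcript_potential_sites(tx)
        vs = [
            mk_variant(tx, 10, MISSENSE),
            mk_variant(tx, 20, MISSENSE),
            mk_variant(tx, 30, SYNONYMOUS),
            mk_variant(tx, 40, SYNONYMOUS),
        ]
        c = genic_dnds(tx, vs)
        assert (c.n_obs, c.s_obs) == (2, 2)
        assert c.dnds == pytest.approx((2 / N) / (2 / S))

    def test_distinct_sites_not_alleles(self, rng):
        tx = make_transcript(600, rng, "T1")
        vs = [
            mk_variant(tx, 10, MISSENSE, alt="A"),
            mk_variant(tx, 10, MISSENSE, alt="G"),  # same site, second allele
            mk_variant(tx, 10, SYNONYMOUS, alt="C"),  # contributes to both classes
            mk_variant(tx, 50, SYNONYMOUS),
            mk_variant(tx, 60, NONSENSE),  # counts in neither
        ]
        c = genic_dnds(tx, vs)
        assert (c.n_obs, c.s_obs) == (1, 2)

    def test_no_missense_gives_zero_with_flag(self, rng):
        tx = make_transcript(600, rng, "T1")
        c = genic_dnds(tx, [mk_variant(tx, 30, SYNONYMOUS)])
        assert c.dnds == 0.0
        assert "no_missense" in c.flags

    def test_zero_synonymous_is_undefined(self, rng):
        tx = make_transcript(600, rng, "T1")
        c = genic_dnds(tx, [mk_variant(tx, 10, MISSENSE)])
        assert c.dnds is None
        assert "low_synonymous" in c.flags

    def test_pseudocount_always_defined(self, rng):
        tx = make_transcript(600, rng, "T1")
        c = genic_dnds(tx, [], pseudocount=True)
        assert c.dnds is not None and c.dnds > 0

    def test_wrong_transcript_rejected(self, rng):
        tx = make_transcript(600, rng, "T1")
        other = make_transcript(600, rng, "T2")
        with pytest.raises(ValueError, match="T2"):
            genic_dnds(tx, [mk_variant(other, 10, MISSENSE)])


class TestCompareGeneSets:
    def _constraints(self, values, gene_prefix):
        from mdrscan.dnds import GeneConstraint

        return [
            GeneConstraint(f"{gene_prefix}{i}", f"{gene_prefix}{i}", 300, 200.0, 100.0, 2, 2, dnds=v)
            for i, v in enumerate(values)
        ]

    def test_identical_distributions_large_p(self):
        cs = self._constraints([0.1, 0.2, 0.3], "A") + self._constraints(
            [0.1, 0.2, 0.3], "B"
        )
        labels = {c.gene_symbol: c.gene_symbol[0] for c in cs}
        res = compare_gene_sets(cs, labels)
        assert res.test == "wilcoxon"
        assert res.pvalue > 0.5

    def test_depleted_category_separates(self, rng):
        """Genes simulated at dN/dS 0.2 vs 1.0 split with p < 0.01."""
        from mdrscan.dnds import genic_dnds

        constraints, labels = [], {}
        for cat, ratio in (("depleted", 0.2), ("neutral", 1.0)):
            for i in range(50):
                tx = make_transcript(1500, rng, f"{cat}{i}")
                vs = simulate_population_variants(tx, ratio * 0.2, 0.2, rng)
                constraints.append(genic_dnds(tx, vs))
                labels[tx.gene_symbol] = cat
        res = compare_gene_sets(constraints, labels)
        med = res.summaries["median"]
        assert med["depleted"] < med["neutral"]
        assert res.pvalue < 0.01

    def test_three_categories_use_kruskal(self):
        cs = (
            self._constraints([0.1, 0.2, 0.3], "A")
            + self._constraints([0.2, 0.3, 0.4], "B")
            + self._constraints([0.3, 0.4, 0.5], "C")
        )
        labels = {c.gene_symbol: c.gene_symbol[0] for c in cs}
        assert compare_gene_sets(cs, labels).test == "kruskal"

    def test_insufficient_categories_error(self):
        cs = self._constraints([0.1, 0.2, 0.3], "A")
        with pytest.raises(ValueError, match="categories"):
            compare_gene_sets(cs, {c.gene_symbol: "A" for c in cs})

    def test_undefined_dnds_excluded_and_reported(self):
        cs = self._constraints([0.1, 0.2, None, 0.3], "A") + self._constraints(
            [0.2, 0.3, 0.4], "B"
        )
        labels = {c.gene_symbol: c.gene_symbol[0] for c in cs}
        res = compare_gene_sets(cs, labels)
        assert res.excluded == ["A2"]


def test_recovery_is_monotone_in_missense_rate():
    """Averaged over seeds, estimated dN/dS is non-decreasing in lambda_m."""
    from mdrscan.studies import dnds_recovery_study

    est = dnds_recovery_study(
        20240901, ratios=(1 / 3, 2 / 3, 4 / 3, 2.0), n_seeds=6, cds_length=9000
    )
    values = [est[r] for r in sorted(est)]
    assert values == sorted(values)
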