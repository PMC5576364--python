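"""Synthetic-data generator: laws, planted truth, determinism."""

import numpy as np
import pytest

from mdrscan.dnds import transcript_potential_sites
from mdrscan.prioritiser import annotate_trio
from mdrscan.synthetic import (
    SimulationConfig,
    TrioSpec,
    blockwise_missense_sites,
    make_transcript,
    rare_maf,
    regular_synonymous_sites,
    simulate_exome,
    simulate_population_variants,
    simulate_trio,
)
from mdrscan.variant_model import (
    MISSENSE,
    SYNONYMOUS,
    annotate_variant,
    CODON_TO_AA,
)


class TestMakeTranscript:
    def test_structure(self):
        tx = make_transcript(300, 1)
        assert len(tx.cds_seq) == 300
        assert tx.cds_seq.startswith("ATG")
        assert CODON_TO_AA[tx.cds_seq[-3:]] == "*"
        assert not tx.has_internal_stop

    def test_deterministic_under_seed(self):
        assert make_transcript(300, 42).cds_seq == make_transcript(300, 42).cds_seq

    @pytest.mark.parametrize("bad", [59, 61, 30])
    def test_invalid_length_rejected(self, bad):
        with pytest.raises(ValueError):
            make_transcript(bad, 1)


class TestSimulatePopulationVariants:
    def test_zero_missense_rate(self, rng):
        tx = make_transcript(3000, rng)
        vs = simulate_population_variants(tx, 0.0, 0.2, rng)
        assert vs and all(v.consequence == SYNONYMOUS for v in vs)

    def test_planted_interval_fully_depleted(self, rng):
        tx = make_transcript(3000, rng)
        vs = simulate_population_variants(
            tx, 0.3, 0.2, rng, planted_interval=(1000, 1600), epsilon=0.0
        )
        assert not any(
            1000 <= v.cds_pos - 1 < 1600 for v in vs if v.consequence == MISSENSE
        )

    def test_rates_validated(self, rng):
        tx = make_transcript(300, rng)
        with pytest.raises(ValueError):
            simulate_population_variants(tx, 1.5, 0.2, rng)

    def test_consequence_labels_match_annotation(self, rng):
        """Placement never lies about the consequence class."""
        tx = make_transcript(1500, rng)
        for v in simulate_population_variants(tx, 0.1, 0.1, rng):
            redone = annotate_variant(tx, v.cds_pos, v.alt)
            assert redone.consequence == v.consequence or redone.consequence == "start_lost"

    def test_variant_count_law(self):
        """Mean synonymous variant count / S_sites is within 3 SE of lambda_s,
        and nonsynonymous count / N_sites likewise of lambda_m."""
        tx = make_transcript(3000, 5)
        N, S = transcript_potential_sites(tx)
        lam_s, lam_m, n_seeds = 0.2, 0.1, 100
        syn_counts, nonsyn_counts = [], []
        for i in range(n_seeds):
            rng = np.random.default_rng(1000 + i)
            vs = simulate_population_variants(tx, lam_m, lam_s, rng)
            syn_counts.append(sum(v.consequence == SYNONYMOUS for v in vs))
            nonsyn_counts.append(sum(v.consequence != SYNONYMOUS for v in vs))
        for counts, lam, sites in ((syn_counts, lam_s, S), (nonsyn_counts, lam_m, N)):
            rate = np.asarray(counts) / sites
            se = rate.std(ddof=1) / np.sqrt(n_seeds)
            assert abs(rate.mean() - lam) < 3 * se + 1e-12

    def test_determinism(self):
        tx = make_transcript(1500, 3)
        a = simulate_population_variants(tx, 0.1, 0.2, np.random.default_rng(9))
        b = simulate_population_variants(tx, 0.1, 0.2, np.random.default_rng(9))
        assert [(v.cds_pos, v.alt, v.maf) for v in a] == [
            (v.cds_pos, v.alt, v.maf) for v in b
        ]


class TestStructuredFixtures:
    def test_regular_synonymous_density(self, rng):
        tx = make_transcript(3000, rng)
        syn = regular_synonymous_sites(tx, 25, rng)
        assert all(v.consequence == SYNONYMOUS for v in syn)
        assert len(syn) == pytest.approx(3000 / 25, abs=3)
        gaps = np.diff(sorted(v.cds_pos for v in syn))
        assert gaps.max() < 50

    def test_blockwise_missense_gap_bound(self, rng):
        tx = make_transcript(1998, rng)
        mis = blockwise_missense_sites(tx, 50, rng)
        assert all(v.consequence == MISSENSE for v in mis)
        pos = sorted(v.cds_pos for v in mis)
        assert np.diff(pos).max() < 100  # one site per 50 bp block

    def test_rare_maf_spectrum(self, rng):
        mafs = rare_maf(rng, 1000)
        assert mafs.min() >= 1e-5 and mafs.max() <= 5e-3


class TestSimulateTrio:
    def _run(self, seed=11, n_background=50):
        config = SimulationConfig(
            seed=seed,
            n_transcripts=30,
            cds_length_range=(900, 1800),
            planted_mdrs={0: (300, 750)},
            trio=TrioSpec(causal_transcript="SYNTX0000", n_background=n_background),
        )
        sim = simulate_exome(config)
        trio = simulate_trio(sim.transcripts, config, planted=sim.planted)
        return sim, trio

    def test_filtered_count_is_exact(self):
        from mdrscan.prioritiser import filter_rare_coding

        _, trio = self._run(n_background=50)
        # exactly the background variants plus the single causal survive
        assert len(filter_rare_coding(trio.proband)) == 51

    def test_causal_is_de_novo_by_construction(self):
        sim, trio = self._run()
        truth = trio.truth["causal"]
        classes = annotate_trio(trio.proband, trio.mother, trio.father)
        key = (truth["transcript_id"], truth["cds_pos"], truth["alt"])
        assert classes[key] == "de_novo"
        s, e = sim.planted[truth["transcript_id"]]
        assert s <= truth["cds_pos"] - 1 < e

    def test_background_carried_by_exactly_one_parent(self):
        _, trio = self._run()
        mkeys = {v.key for v in trio.mother}
        fkeys = {v.key for v in trio.father}
        for rec in trio.truth["background"]:
            v = next(
                v for v in trio.proband
                if v.transcript_id == rec["transcript_id"]
                and v.cds_pos == rec["cds_pos"]
            )
            assert (v.key in mkeys) != (v.key in fkeys)

    def test_causal_transcript_must_have_planted_interval(self):
        config = SimulationConfig(
            seed=1, n_transcripts=5, cds_length_range=(900, 1200),
            trio=TrioSpec(causal_transcript="SYNTX0000"),
        )
        sim = simulate_exome(config)
        with pytest.raises(ValueError, match="planted"):
            simulate_trio(sim.transcripts, config, planted={})

    def test_determinism(self):
        _, t1 = self._run(seed=21)
        _, t2 = self._run(seed=21)
        assert [v.key for v in t1.proband] == [v.key for v in t2.proband]
        assert t1.truth == t2.truth


def test_simulate_exome_reproducible_and_planted_respected():
    config = SimulationConfig(
        seed=99, n_transcripts=10, cds_length_range=(900, 1500),
        planted_mdrs={2: (150, 600)},
    )
    a, b = simulate_exome(config), simulate_exome(config)
    assert {t: tx.cds_seq for t, tx in a.transcripts.items()} == {
        t: tx.cds_seq for t, tx in b.transcripts.items()
    }
    tid = "SYNTX0002"
    assert [v.key for v in a.variants_by_tx[tid]] == [v.key for v in b.variants_by_tx[tid]]
    assert not any(
        150 <= v.cds_pos - 1 < 600
        for v in a.variants_by_tx[tid]
        if v.consequence == MISSENSE
    )
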