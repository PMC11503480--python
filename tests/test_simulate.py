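"""Tetramer signatures, fragmentation, bin simulation, synthetic world."""

import numpy as np
import pytest

from magqc.profiles import bray_curtis_similarity, profile_bray_curtis_dissimilarity, toy_annotate
from magqc.simulate import (
    Genome,
    SimulationError,
    fragment_genome,
    generate_synthetic_world,
    read_manifest,
    select_contaminants,
    simulate_bin,
    tetramer_profile,
    write_bins,
)
from datetime import date


def _genome(gid, sequence, clade=0):
    from magqc.profiles import DomainProfile

    return Genome(
        genome_id=gid,
        sequence=sequence,
        profile=DomainProfile(gid, {}),
        superkingdom="bacteria",
        taxid=100,
        release_date=date(2020, 1, 1),
        clade=clade,
    )


def _random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestTetramerProfile:
    def test_single_window(self):
        v = tetramer_profile("AAAA")
        assert v.shape == (136,)
        assert v.sum() == pytest.approx(1.0)
        assert v.max() == 1.0  # all mass on canonical AAAA

    def test_reverse_complement_canonicalized(self):
        # windows: AAAA, AAAT, AATT, ATTT, TTTT; TTTT canonicalizes to AAAA
        v = tetramer_profile("AAAATTTT")
        aaaa = tetramer_profile("AAAA")
        bin_aaaa = int(np.argmax(aaaa))
        assert v[bin_aaaa] == pytest.approx(2 / 5)

    def test_ambiguous_windows_skipped(self):
        # of the 5 windows in "ACGNACGT", the four containing N are skipped
        v = tetramer_profile("ACGNACGT")
        assert v.sum() == pytest.approx(1.0)
        w = tetramer_profile("ACGT")  # the only valid window
        assert np.array_equal(v, w)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tetramer_profile("ACG")

    def test_strand_invariance(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 2000)
        from magqc.profiles import reverse_complement

        assert np.allclose(
            tetramer_profile(seq), tetramer_profile(reverse_complement(seq))
        )


class TestFragmentGenome:
    def test_exact_division(self):
        assert len(fragment_genome("A" * 100, 20)) == 5

    def test_tail_kept_at_quarter_length(self):
        frags = fragment_genome("A" * 105, 20)
        assert len(frags) == 6
        assert len(frags[-1]) == 5

    def test_short_tail_dropped(self):
        frags = fragment_genome("A" * 104, 20)
        assert len(frags) == 5
        assert all(len(f) == 20 for f in frags)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fragment_genome("", 20)

    def test_fragments_reassemble_prefix(self):
        seq = "ACGTT" * 50
        frags = fragment_genome(seq, 60)
        assert "".join(frags) == seq[: sum(map(len, frags))]


class TestSelectContaminants:
    def test_identical_composition_eligible(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 5000, gc=0.5))
        twin = _genome("t", q.sequence)
        assert [g.genome_id for g in
                select_contaminants(q, [twin], np.random.default_rng(1))] == ["t"]

    def test_dissimilar_composition_rejected(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 5000, gc=0.7))
        pool = [_genome(f"p{i}", _random_seq(rng, 5000, gc=0.3)) for i in range(3)]
        with pytest.raises(SimulationError, match="unusable"):
            select_contaminants(q, pool, np.random.default_rng(1))

    def test_query_itself_excluded(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 5000))
        with pytest.raises(SimulationError):
            select_contaminants(q, [q], np.random.default_rng(1))

    def test_fixed_seed_reproducible_order(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 5000))
        pool = [_genome(f"p{i}", _random_seq(rng, 5000)) for i in range(6)]
        order1 = [g.genome_id for g in
                  select_contaminants(q, pool, np.random.default_rng(42))]
        order2 = [g.genome_id for g in
                  select_contaminants(q, pool, np.random.default_rng(42))]
        assert order1 == order2


class TestSimulateBin:
    def test_completeness_quantization(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 100_000))
        sb = simulate_bin(
            q, [], np.random.default_rng(1), fragment_length=20_000,
            comp_range=(0.8, 0.8), cont_range=(0.0, 0.0),
        )
        assert sb.truth_completeness == pytest.approx(0.8)
        assert len(sb.contigs) == 4  # 4 of 5 fragments

    def test_zero_contamination_no_contaminants(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 100_000))
        sb = simulate_bin(q, [], np.random.default_rng(1),
                          cont_range=(0.0, 0.0))
        assert sb.contaminant_ids == []
        assert sb.truth_contamination == 0.0

    def test_full_bin_reassembles_genome(self, small_world):
        g = small_world.genomes[0]
        sb = simulate_bin(
            g, [], np.random.default_rng(2), fragment_length=5_000,
            comp_range=(1.0, 1.0), cont_range=(0.0, 0.0),
        )
        assert sb.truth_completeness == 1.0
        profile = toy_annotate(sb.contigs, small_world.catalog, "bin")
        assert profile.counts == g.profile.counts

    def test_truth_bookkeeping_exact(self, small_world):
        rng = np.random.default_rng(3)
        g = small_world.genomes[0]
        pool = small_world.genomes
        for i in range(5):
            sb = simulate_bin(g, pool, rng, fragment_length=5_000)
            L = len(g.sequence)
            assert sb.query_bases() / L == pytest.approx(sb.truth_completeness)
            assert sb.contaminant_bases() / L == pytest.approx(
                sb.truth_contamination
            )
            for src, _ in sb.provenance:
                assert src == g.genome_id or src in sb.contaminant_ids

    def test_unrealizable_contamination_raises(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 100_000))
        tiny = _genome("tiny", q.sequence[:5_000])
        with pytest.raises(SimulationError, match="exhausted"):
            simulate_bin(
                q, [tiny], np.random.default_rng(1), fragment_length=5_000,
                cont_range=(0.3, 0.3),
            )

    def test_native_contig_passthrough(self):
        rng = np.random.default_rng(0)
        q = _genome("q", _random_seq(rng, 50_000))
        sb = simulate_bin(
            q, [], np.random.default_rng(1), fragment_length=0,
            comp_range=(1.0, 1.0), cont_range=(0.0, 0.0),
        )
        assert sb.contigs == [q.sequence]


class TestBinIO:
    def test_write_read_manifest_round_trip(self, tmp_path, small_world):
        rng = np.random.default_rng(4)
        g = small_world.genomes[0]
        bins = [
            simulate_bin(g, small_world.genomes, rng, fragment_length=5_000,
                         bin_id=f"b{i}", seed=4)
            for i in range(3)
        ]
        write_bins(bins, tmp_path / "bins")
        rows = read_manifest(tmp_path / "bins" / "manifest.tsv")
        assert [r["bin_id"] for r in rows] == ["b0", "b1", "b2"]
        for sb, row in zip(bins, rows):
            assert row["truth_completeness"] == pytest.approx(sb.truth_completeness)
            assert row["truth_contamination"] == pytest.approx(sb.truth_contamination)
            assert row["source"] == g.genome_id
            assert row["contaminants"] == sb.contaminant_ids
        fasta = (tmp_path / "bins" / "b0.fasta").read_text()
        assert fasta.startswith(f">b0|src={g.genome_id}|frag=")


class TestSyntheticWorld:
    def test_profiles_round_trip_through_annotation(self, small_world):
        for g in small_world.genomes[:3]:
            observed = toy_annotate([g.sequence], small_world.catalog, g.genome_id)
            assert observed.counts == g.profile.counts

    def test_same_clade_profiles_more_similar(self, small_world):
        by_clade = {}
        for g in small_world.genomes:
            by_clade.setdefault(g.clade, []).append(g)
        within, across = [], []
        clades = sorted(by_clade)
        for c in clades:
            gs = by_clade[c]
            within.append(
                1 - profile_bray_curtis_dissimilarity(gs[0].profile, gs[1].profile)
            )
            other = by_clade[clades[(clades.index(c) + 1) % len(clades)]][0]
            across.append(
                1 - profile_bray_curtis_dissimilarity(gs[0].profile, other.profile)
            )
        assert np.mean(within) > np.mean(across)

    def test_same_clade_tetramer_similarity_high(self, small_world):
        by_clade = {}
        for g in small_world.genomes:
            by_clade.setdefault(g.clade, []).append(g)
        for gs in by_clade.values():
            assert bray_curtis_similarity(gs[0].tetramers, gs[1].tetramers) >= 0.8

    def test_core_families_mostly_single_copy(self, small_world):
        n = len(small_world.genomes)
        for fam in small_world.core_families:
            single = sum(
                1 for g in small_world.genomes if g.profile.get(fam) == 1
            )
            assert single / n >= 0.95

    def test_fixed_seed_reproducible(self):
        kw = dict(n_genomes=4, n_core_families=30, n_accessory_families=30,
                  genome_length=30_000, n_clades=2, seed=99)
        w1 = generate_synthetic_world(**kw)
        w2 = generate_synthetic_world(**kw)
        assert w1.catalog == w2.catalog
        assert all(
            a.sequence == b.sequence and a.profile.counts == b.profile.counts
            for a, b in zip(w1.genomes, w2.genomes)
        )

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_synthetic_world(
                n_genomes=2, n_core_families=50, n_accessory_families=50,
                genome_length=1_000, n_clades=1, seed=0,
            )

    def test_release_dates_span_three_eras(self, small_world):
        dates = sorted(g.release_date for g in small_world.genomes)
        assert dates[0].year == 2019
        assert any(date(2021, 1, 1) <= d < date(2023, 1, 1) for d in dates)
        assert dates[-1] >= date(2023, 6, 1)

    def test_taxonomy_is_rooted_tree(self, small_world):
        tax = small_world.taxonomy
        assert tax[1] == 1
        for child, parent in tax.items():
            node, hops = child, 0
            while tax[node] != node:
                node = tax[node]
                hops += 1
                assert hops < 100
            assert node == 1
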