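"""Synthetic genome generation: planting, recombination, fragmentation, truth."""

import numpy as np
import pytest

from tripscan.align import reverse_complement
from tripscan.reference import CANONICAL_FLANKS, gc_fraction
from tripscan.simulate import (
    LocusSpec,
    SimulationConfig,
    generate_background,
    simulate_cohort,
    simulate_genome,
    write_genome,
)


class TestBackground:
    def test_seeded_determinism(self):
        assert generate_background(10_000, 0.5, 42) == generate_background(10_000, 0.5, 42)

    def test_gc_one_uses_only_g_and_c(self):
        assert set(generate_background(2_000, 1.0, 0)) <= {"G", "C"}

    def test_empirical_gc_close_to_requested(self):
        seq = generate_background(100_000, 0.63, 7)
        assert abs(gc_fraction(seq) - 0.63) < 0.01

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_background(100, 1.5, 0)


class TestPlanting:
    def test_locus_e_gene_boundaries_at_published_offsets(self, registry):
        cfg = SimulationConfig(seed=0, genome_length=30_000, loci=(LocusSpec("E", 10_000),))
        sim = simulate_genome(cfg, registry)
        (hit,) = sim.truth.hits
        left_gene, left_off, right_gene, right_off = CANONICAL_FLANKS["E"]
        by_name = {f.gene_name: f for f in sim.features}
        assert hit.start - by_name[left_gene].end - 1 == left_off == 38
        assert by_name[right_gene].start - hit.end - 1 == right_off == 124
        (call,) = sim.truth.calls
        assert (call.left_gene, call.left_distance) == ("copA", 38)
        assert (call.right_gene, call.right_distance) == ("ybaP", 124)

    def test_zero_divergence_plants_exact_registry_copy(self, registry):
        cfg = SimulationConfig(seed=1, genome_length=30_000, loci=(LocusSpec("C", 12_000, strand="-"),))
        sim = simulate_genome(cfg, registry)
        (hit,) = sim.truth.hits
        segment = sim.contigs["chr"][hit.start - 1 : hit.end]
        assert reverse_complement(segment) == registry["C"].sequence

    def test_divergence_realized_within_binomial_band(self, registry):
        cfg = SimulationConfig(seed=2, genome_length=30_000, loci=(LocusSpec("A", 12_000, divergence=0.05),))
        sim = simulate_genome(cfg, registry)
        (hit,) = sim.truth.hits
        segment = sim.contigs["chr"][hit.start - 1 : hit.end]
        ref = registry["A"].sequence
        hamming = sum(a != b for a, b in zip(segment, ref)) / len(ref)
        assert abs(hamming - 0.05) <= 0.02

    def test_planted_termini_never_mutated(self, registry):
        cfg = SimulationConfig(seed=3, genome_length=30_000, loci=(LocusSpec("D", 12_000, divergence=0.15),))
        sim = simulate_genome(cfg, registry)
        (hit,) = sim.truth.hits
        segment = sim.contigs["chr"][hit.start - 1 : hit.end]
        assert segment[:10] == registry["D"].sequence[:10]
        assert segment[-10:] == registry["D"].sequence[-10:]

    def test_overlapping_plants_rejected(self, registry):
        cfg = SimulationConfig(
            seed=4, genome_length=30_000, loci=(LocusSpec("A", 10_000), LocusSpec("C", 10_500))
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(cfg, registry)


def ac_config(seed=10, invert=True, strand_a="+", strand_c="-"):
    return SimulationConfig(
        seed=seed,
        genome_length=90_000,
        loci=(LocusSpec("A", 20_000, strand=strand_a), LocusSpec("C", 60_000, strand=strand_c)),
        inversions=(("A", "C"),) if invert else (),
    )


class TestInversion:
    def test_reciprocal_junction_gene_pairs(self, registry):
        sim = simulate_genome(ac_config(), registry)
        pairs = {e.junction_pair for e in sim.truth.events}
        assert pairs == {frozenset({"aqpZ", "yohI"}), frozenset({"ybjE", "yohG"})}
        assert all(e.paired for e in sim.truth.events)

    def test_span_matches_interval_arithmetic_on_truth_hits(self, registry):
        sim = simulate_genome(ac_config(), registry)
        h1, h2 = sorted(sim.truth.hits, key=lambda h: h.start)
        for e in sim.truth.events:
            assert e.span == h2.end - h1.start + 1

    def test_base_content_conserved_up_to_complementation(self, registry):
        plain = simulate_genome(ac_config(invert=False), registry).contigs["chr"]
        inverted = simulate_genome(ac_config(invert=True), registry).contigs["chr"]
        assert len(plain) == len(inverted)
        for pair in ("AT", "GC"):
            assert sum(plain.count(b) for b in pair) == sum(inverted.count(b) for b in pair)

    def test_double_inversion_restores_gene_order_and_strands(self, registry):
        cfg = ac_config()
        once = simulate_genome(cfg, registry)
        twice_cfg = SimulationConfig(**{**cfg.__dict__, "inversions": (("A", "C"), ("A", "C"))})
        twice = simulate_genome(twice_cfg, registry)
        plain = simulate_genome(ac_config(invert=False), registry)
        order = lambda sim: [(f.gene_name, f.strand) for f in sorted(sim.features, key=lambda f: f.start)]
        assert order(twice) == order(plain)
        assert order(once) != order(plain)
        assert {c.locus_label for c in twice.truth.calls} == {"A", "C"}

    def test_direct_orientation_rejected_for_inversion(self, registry):
        with pytest.raises(ValueError, match="direct orientation"):
            simulate_genome(ac_config(strand_c="+"), registry)

    def test_emitted_gff3_round_trips_the_feature_table(self, registry, tmp_path):
        from tripscan.io import read_gff3

        sim = simulate_genome(ac_config(), registry)
        paths = write_genome(sim, tmp_path)
        loaded = read_gff3(paths["gff3"])
        assert sorted((f.gene_name, f.start, f.end, f.strand) for f in loaded) == sorted(
            (f.gene_name, f.start, f.end, f.strand) for f in sim.features
        )


class TestDeletion:
    def test_direct_repeats_leave_single_unpaired_junction(self, registry):
        cfg = SimulationConfig(
            seed=20,
            genome_length=90_000,
            loci=(LocusSpec("A", 20_000, strand="+"), LocusSpec("C", 60_000, strand="+")),
            deletions=(("A", "C"),),
        )
        sim = simulate_genome(cfg, registry)
        assert len(sim.truth.hits) == 1
        (event,) = sim.truth.events
        assert event.junction_pair == frozenset({"aqpZ", "yohG"})
        assert not event.paired and event.span is None
        # excised: the inner gene pair and the intervening sequence
        names = {f.gene_name for f in sim.features}
        assert names == {"aqpZ", "yohG"}

    def test_inverted_orientation_rejected_for_deletion(self, registry):
        cfg = SimulationConfig(
            seed=21,
            genome_length=90_000,
            loci=(LocusSpec("A", 20_000, strand="+"), LocusSpec("C", 60_000, strand="-")),
            deletions=(("A", "C"),),
        )
        with pytest.raises(ValueError, match="inverted orientation"):
            simulate_genome(cfg, registry)


class TestFragmentation:
    def test_single_contig_is_identity(self, registry):
        cfg = SimulationConfig(seed=30, genome_length=40_000, loci=(LocusSpec("B", 15_000, strand="-"),), n_contigs=1)
        sim = simulate_genome(cfg, registry)
        assert list(sim.contigs) == ["chr"]

    def test_total_length_conserved(self, registry):
        cfg = SimulationConfig(
            seed=31,
            genome_length=60_000,
            loci=(LocusSpec("A", 15_000), LocusSpec("D", 40_000)),
            n_contigs=5,
        )
        sim = simulate_genome(cfg, registry)
        assert sum(len(s) for s in sim.contigs.values()) == 60_000
        assert len(sim.contigs) == 5

    def test_repeats_never_cut_and_coordinates_remapped(self, registry):
        cfg = SimulationConfig(
            seed=32,
            genome_length=60_000,
            loci=(LocusSpec("A", 15_000), LocusSpec("E", 40_000)),
            n_contigs=6,
        )
        sim = simulate_genome(cfg, registry)
        assert len(sim.truth.hits) == 2
        for h in sim.truth.hits:
            seg = sim.contigs[h.contig_id][h.start - 1 : h.end]
            ref = registry[next(iter(h.allowed_types))].sequence
            assert (seg if h.strand == "+" else reverse_complement(seg)) == ref

    def test_lost_flank_marks_call_unplaced(self, registry):
        # severed genes are dropped from the annotation, so the expected call
        # for a repeat whose flank gene is cut must be unplaced
        cfg = SimulationConfig(
            seed=33,
            genome_length=30_000,
            loci=(LocusSpec("A", 14_000),),
            n_contigs=12,
        )
        sim = simulate_genome(cfg, registry)
        for call in sim.truth.calls:
            h = sim.truth.hits[call.hit_index]
            genes_on_contig = {f.gene_name for f in sim.features if f.contig_id == h.contig_id}
            if call.locus_label == "unplaced":
                assert not {"aqpZ", "ybjE"} <= genes_on_contig or call.left_gene is None or call.right_gene is None
            else:
                assert call.locus_label == "A"

    def test_too_many_contigs_rejected(self, registry):
        cfg = SimulationConfig(seed=34, genome_length=2_000, loci=(), n_contigs=3_000)
        with pytest.raises(ValueError):
            simulate_genome(cfg, registry)


class TestDeterminism:
    def test_identical_configs_give_byte_identical_outputs(self, registry, tmp_path):
        cfg = ac_config(seed=40)
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        p1 = write_genome(simulate_genome(cfg, registry), tmp_path / "a")
        p2 = write_genome(simulate_genome(cfg, registry), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_cohort_is_seed_deterministic(self, registry):
        a = simulate_cohort(3, seed=9, genome_length=50_000, registry=registry)
        b = simulate_cohort(3, seed=9, genome_length=50_000, registry=registry)
        assert [s.contigs for s in a] == [s.contigs for s in b]
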