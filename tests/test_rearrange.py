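"""Junction detection, reciprocal pairing and event tallies."""

import numpy as np

from tests.conftest import make_typed_hit
from tripscan.loci import LocusCall
from tripscan.rearrange import RearrangementEvent, detect_junctions, pair_events, tally_events
from tripscan.reference import CANONICAL_PAIRS

# published per-subtype event counts of the 6725-genome survey
SURVEY_SUBTYPES = [
    ({"aqpZ", "yohI"}, 68),
    ({"ybjE", "yohG"}, 58),
    ({"aqpZ", "yohG"}, 7),
    ({"ybjE", "yohI"}, 4),
    ({"ybaP", "aqpZ"}, 3),
    ({"copA", "ybjE"}, 3),
    ({"ybjE", "ycdN"}, 2),
    ({"aqpZ", "putP"}, 2),
    ({"aqpZ", "ycdN"}, 1),
    ({"putP", "yohG"}, 2),
    ({"putP", "yohI"}, 1),
    ({"ycdN", "yohI"}, 2),
    ({"ybjE", "alx"}, 1),
    ({"aqpZ", "alx"}, 1),
    ({"copA", "yohI"}, 1),
]


def make_call(left, right, label="hybrid", start=100, end=365, genome="g"):
    hit = make_typed_hit(start, end, genome_id=genome)
    pair = frozenset({left, right}) if label == "hybrid" else None
    return LocusCall(hit, left, right, 10, 10, label, pair)


def make_event(pair, genome="g", contig="chr", start=100, end=365, locus_pair=None):
    from tripscan.reference import GENE_TO_LOCUS

    pair = frozenset(pair)
    return RearrangementEvent(
        genome_id=genome,
        contig_id=contig,
        junction_pair=pair,
        locus_pair=locus_pair or frozenset(GENE_TO_LOCUS[g] for g in pair),
        repeat_type="A",
        orientation="forward",
        repeat_start=start,
        repeat_end=end,
    )


class TestDetectJunctions:
    def test_hybrid_call_maps_to_locus_pair(self):
        events = detect_junctions([make_call("ybjE", "yohG")])
        assert len(events) == 1
        assert events[0].locus_pair == frozenset({"A", "C"})

    def test_canonical_calls_yield_no_events(self):
        calls = [make_call("aqpZ", "ybjE", label="A"), make_call("putP", "ycdN", label="B")]
        assert detect_junctions(calls) == []

    def test_one_event_per_hybrid_call(self):
        calls = [make_call("aqpZ", "yohI"), make_call("ybjE", "yohG", start=50_000, end=50_265)]
        assert len(detect_junctions(calls)) == 2

    def test_simulated_inversion_produces_two_events(self, registry):
        from tripscan.pipeline import analyze_genome
        from tripscan.simulate import LocusSpec, SimulationConfig, simulate_genome

        cfg = SimulationConfig(
            seed=5,
            genome_length=80_000,
            loci=(LocusSpec("A", 15_000, strand="+"), LocusSpec("C", 55_000, strand="-")),
            inversions=(("A", "C"),),
        )
        sim = simulate_genome(cfg, registry)
        result = analyze_genome(sim.genome_id, sim.contigs, sim.features, registry)
        assert len(result.events) == 2
        assert {e.junction_pair for e in result.events} == {
            frozenset({"aqpZ", "yohI"}),
            frozenset({"ybjE", "yohG"}),
        }

    def test_locus_pairs_stay_within_the_ten_possible(self):
        rng = np.random.default_rng(0)
        genes = sorted({g for p in CANONICAL_PAIRS.values() for g in p})
        possible = {
            frozenset({a, b}) for a in "ABCDE" for b in "ABCDE" if a != b
        }
        for _ in range(50):
            g1, g2 = rng.choice(genes, size=2, replace=False)
            from tripscan.loci import assign_locus

            label, pair = assign_locus(str(g1), str(g2))
            if label == "hybrid":
                (ev,) = detect_junctions([make_call(str(g1), str(g2))])
                assert ev.locus_pair in possible


class TestPairEvents:
    def test_reciprocal_junctions_paired_with_inclusive_span(self):
        e1 = make_event({"aqpZ", "yohI"}, start=10_000, end=10_268)
        e2 = make_event({"ybjE", "yohG"}, start=30_003, end=30_272)
        paired = pair_events([e1, e2])
        assert all(e.paired for e in paired)
        assert {e.span for e in paired} == {30_272 - 10_000 + 1}

    def test_exclusive_span_option(self):
        e1 = make_event({"aqpZ", "yohI"}, start=10_000, end=10_268)
        e2 = make_event({"ybjE", "yohG"}, start=30_003, end=30_272)
        paired = pair_events([e1, e2], inclusive_span=False)
        assert {e.span for e in paired} == {30_003 - 10_268 - 1}

    def test_single_hybrid_stays_unpaired(self):
        (only,) = pair_events([make_event({"aqpZ", "yohI"})])
        assert not only.paired
        assert only.span is None

    def test_same_subtype_twice_does_not_pair(self):
        e1 = make_event({"aqpZ", "yohI"}, start=10_000, end=10_268)
        e2 = make_event({"aqpZ", "yohI"}, start=30_000, end=30_268)
        assert not any(e.paired for e in pair_events([e1, e2]))

    def test_two_disjoint_inversions_pair_independently(self, registry):
        from tripscan.pipeline import analyze_genome
        from tripscan.simulate import LocusSpec, SimulationConfig, simulate_genome

        cfg = SimulationConfig(
            seed=6,
            genome_length=160_000,
            loci=(
                LocusSpec("A", 15_000, strand="+"),
                LocusSpec("C", 50_000, strand="-"),
                LocusSpec("D", 90_000, strand="+"),
                LocusSpec("E", 130_000, strand="-"),
            ),
            inversions=(("A", "C"), ("D", "E")),
        )
        sim = simulate_genome(cfg, registry)
        result = analyze_genome(sim.genome_id, sim.contigs, sim.features, registry)
        assert len(result.events) == 4
        assert all(e.paired for e in result.events)
        spans = {e.locus_pair: e.span for e in result.events}
        truth_spans = {e.locus_pair: e.span for e in sim.truth.events}
        assert spans == truth_spans


class TestTallyEvents:
    def test_survey_subtype_counts_total_156_with_ac_at_88_percent(self):
        events = []
        for i, (pair, count) in enumerate(SURVEY_SUBTYPES):
            for j in range(count):
                events.append(make_event(pair, genome=f"g{i}_{j}"))
        tally = tally_events(events)
        assert tally.total == 156
        assert tally.by_locus_pair[frozenset({"A", "C"})] == 137
        assert tally.share_percent[frozenset({"A", "C"})] == 88

    def test_empty_event_list(self):
        tally = tally_events([])
        assert tally.total == 0
        assert tally.n_genomes == 0
        assert tally.by_locus_pair == {}

    def test_total_equals_sum_of_subtype_counts(self):
        rng = np.random.default_rng(1)
        pool = [p for p, _ in SURVEY_SUBTYPES]
        events = [make_event(pool[int(i)], genome=f"g{int(i) % 7}") for i in rng.integers(0, len(pool), 40)]
        tally = tally_events(events)
        assert tally.total == sum(tally.by_junction_pair.values()) == 40
        assert tally.n_genomes == len({e.genome_id for e in events})

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        pool = [p for p, _ in SURVEY_SUBTYPES]
        events = [make_event(pool[int(i)]) for i in rng.integers(0, len(pool), 25)]
        shuffled = list(events)
        rng.shuffle(shuffled)
        assert tally_events(events) == tally_events(shuffled)
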