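"""Junction extraction, filtering, motifs, interpolation and units."""

import numpy as np
import pytest

from kfac.alignments import CellAlignmentSet, Read, _parse_cigar
from kfac.splicing_topology import (
    SpliceGraph,
    SpliceJunction,
    aggregate_and_filter,
    analyze_cell,
    extract_junctions,
    infer_units,
    interpolate_transcribed,
    junction_motifs,
)
from kfac.synthetic_data import SimParams, simulate_cells


def _aln(model, reads):
    return CellAlignmentSet("t", model.chrom, reads, model.length)


class TestJunctionExtraction:
    @pytest.mark.parametrize("start,cigar,expected", [
        (1000, "50M200N25M", [(1050, 1250)]),
        (1000, "75M", []),
        (1000, "30M100N20M50N25M", [(1030, 1130), (1150, 1200)]),
        (1000, "5S30M100N40M", [(1030, 1130)]),   # soft clip consumes no reference
        (1000, "30M2D10M100N33M", [(1042, 1142)]),  # deletion consumes reference
    ])
    def test_cigar_walk(self, model, start, cigar, expected):
        read = Read("r", start, _parse_cigar(cigar), "A" * 75)
        junctions = extract_junctions(_aln(model, [read]))
        assert [(j.donor_pos, j.acceptor_pos) for j in junctions] == expected

    def test_ref_blocks_complement_junctions(self, model):
        read = Read("r", 1000, _parse_cigar("30M100N20M50N25M"), "A" * 75)
        assert read.ref_blocks() == [(1000, 1030), (1130, 1150), (1200, 1225)]


class TestAggregateAndFilter:
    def _junctions(self, model, count):
        a, b = model.vk_segments[0], model.vk_segments[1]
        return [SpliceJunction("t", a.end, b.start) for _ in range(count)]

    def test_filter_boundary(self, model):
        kept = aggregate_and_filter(self._junctions(model, 10), model)
        dropped = aggregate_and_filter(self._junctions(model, 9), model)
        assert len(kept.edges) == 1 and not kept.dropped
        assert not dropped.edges and len(dropped.dropped) == 1
        assert dropped.dropped[0].count == 9

    def test_empty_input_gives_empty_graph(self, model):
        graph = aggregate_and_filter([], model)
        assert not graph.edges and not graph.nodes

    def test_min_count_monotonicity(self, model, rng):
        vks = model.vk_segments
        junctions = []
        for _ in range(60):
            i, j = sorted(rng.choice(len(vks), size=2, replace=False))
            junctions += [SpliceJunction("t", vks[i].end, vks[j].start)] * int(rng.integers(1, 25))
        sizes = [len(aggregate_and_filter(junctions, model, min_count=m).edges)
                 for m in range(1, 30)]
        assert sizes == sorted(sizes, reverse=True)

    def test_unannotated_junction_is_intergenic(self, model):
        j = SpliceJunction("t", 500, 900)  # upstream of every segment
        graph = aggregate_and_filter([j] * 12, model)
        assert not graph.edges and len(graph.intergenic) == 1


class TestMotifs:
    def test_sense_and_antisense_planted_junctions_are_canonical(self, model):
        seq = model.reference_sequences["B6"]
        a, b = model.vk_segments[0], model.vk_segments[1]
        left, right, canonical = junction_motifs(SpliceJunction("t", a.end, b.start), seq)
        assert (left, right, canonical) == ("GT", "AG", True)
        left, right, canonical = junction_motifs(
            SpliceJunction("t", a.end + 4, b.start - 4), seq)
        assert (left, right, canonical) == ("CT", "AC", True)

    def test_strand_tagging_from_motifs(self, model):
        a, b = model.vk_segments[0], model.vk_segments[1]
        sense = aggregate_and_filter([SpliceJunction("t", a.end, b.start)] * 10, model)
        anti = aggregate_and_filter([SpliceJunction("t", a.end + 4, b.start - 4)] * 10, model)
        assert {k[2] for k in sense.edges} == {"+"}
        assert {k[2] for k in anti.edges} == {"-"}

    def test_shuffled_sequence_canonical_fraction_matches_chance(self, rng):
        """On random sequence the canonical rate is the dinucleotide-frequency
        expectation p(GT)p(AG) + p(CT)p(AC)."""
        seq = "".join(rng.choice(list("ACGT"), size=200_000))
        # empirical dinucleotide frequencies as the chance oracle
        dinucs = [seq[i:i + 2] for i in range(len(seq) - 1)]
        from collections import Counter
        freq = Counter(dinucs)
        total = len(dinucs)
        p_chance = (freq["GT"] * freq["AG"] + freq["CT"] * freq["AC"]) / total ** 2
        n = 20_000
        hits = 0
        for _ in range(n):
            d = int(rng.integers(2, len(seq) - 1000))
            a = d + int(rng.integers(100, 900))
            hits += junction_motifs(SpliceJunction("t", d, a), seq)[2]
        se = np.sqrt(p_chance * (1 - p_chance) / n)
        assert abs(hits / n - p_chance) < 4 * se + 1e-4

    def test_junction_outside_sequence_errors(self, model):
        with pytest.raises(ValueError):
            junction_motifs(SpliceJunction("t", 0, 10), "ACGT")


def _graph_from_pairs(model, pairs, count=10):
    junctions = []
    for a, b in pairs:
        sa, sb = model.segment(a), model.segment(b)
        junctions += [SpliceJunction("t", sa.end, sb.start)] * count
    return aggregate_and_filter(junctions, model)


class TestInterpolation:
    def test_between_oracle_on_random_edge_sets(self, model, rng):
        """Interpolation equals brute-force between-coordinates enumeration."""
        vks = model.vk_segments
        for _ in range(300):
            k = int(rng.integers(1, 5))
            pairs = []
            for _ in range(k):
                i, j = sorted(rng.choice(len(vks), size=2, replace=False))
                pairs.append((vks[i].id, vks[j].id))
            graph = _graph_from_pairs(model, pairs)
            got, anomalies = interpolate_transcribed(graph, model)
            expect = set(graph.nodes)
            for a, b in pairs:
                sa, sb = model.segment(a), model.segment(b)
                if model.tad_of(sa.start) != model.tad_of(sb.start):
                    continue  # anomalous edge: excluded
                for s in vks:  # brute-force oracle
                    if s.start >= sa.end and s.end <= sb.start:
                        expect.add(s.id)
            assert got == expect

    def test_adjacent_edge_interpolates_nothing(self, model):
        a, b = model.vk_segments[0], model.vk_segments[1]
        graph = _graph_from_pairs(model, [(a.id, b.id)])
        got, _ = interpolate_transcribed(graph, model)
        assert got == {a.id, b.id}

    def test_skip_one_edge_interpolates_the_middle(self, model):
        a, b, c = model.vk_segments[:3]
        graph = _graph_from_pairs(model, [(a.id, c.id)])
        got, _ = interpolate_transcribed(graph, model)
        assert got == {a.id, b.id, c.id}

    def test_cross_tad_edge_flagged_and_excluded(self, model):
        distal = model.vk_segments[0]
        proximal = model.vk_segments[-1]
        graph = _graph_from_pairs(model, [(distal.id, proximal.id)])
        got, anomalies = interpolate_transcribed(graph, model)
        assert len(anomalies) == 1
        assert got == {distal.id, proximal.id}  # observed only, nothing interpolated
        units, anomalies2 = infer_units(graph, model)
        assert units == [] and len(anomalies2) == 1


class TestUnits:
    def test_no_junctions_three_observed_segments_three_singletons(self, model):
        graph = SpliceGraph(cell_id="t")
        observed = {s.id for s in model.vk_segments[:3]}
        units, _ = infer_units(graph, model, observed_segments=observed)
        assert len(units) == 3
        assert all(len(u.segment_ids) == 1 for u in units)

    def test_two_planted_units_in_distinct_tads(self, model):
        params = SimParams(n_cells=30, seed=41, base_error_rate=0.0,
                           p_same_allele_locuswide=0.0,  # guarantees >= 2 units
                           state_probabilities={"poised": 1.0})
        for truth, aln in simulate_cells(model, params):
            _, units, _ = analyze_cell(aln, model)
            assert len(units) == len(truth.transcription_units) >= 2
            assert len({u.tad for u in units}) == len(units)

    def test_full_unit_recovery_against_truth(self, model):
        params = SimParams(n_cells=40, seed=42, base_error_rate=0.0,
                           state_probabilities={"poised": 1.0})
        for truth, aln in simulate_cells(model, params):
            _, units, anomalies = analyze_cell(aln, model)
            assert anomalies == []
            got = sorted((tuple(u.segment_ids), u.span) for u in units)
            want = sorted((tuple(u.segment_ids), u.span)
                          for u in truth.transcription_units)
            assert got == want
            # strand is junction-derived, so it is checkable for spliced units
            want_strand = {tuple(u.segment_ids): u.strand
                           for u in truth.transcription_units if len(u.segment_ids) > 1}
            for u in units:
                if len(u.segment_ids) > 1:
                    assert u.strand == want_strand[tuple(u.segment_ids)]
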