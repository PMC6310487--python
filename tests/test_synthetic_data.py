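"""Generator contracts: determinism, haplotype fidelity, planted structure."""

import filecmp

import numpy as np
import pytest

from kfac.alignments import CellAlignmentSet
from kfac.locus_model import ANTISENSE_OFFSET
from kfac.splicing_topology import extract_junctions, junction_motifs
from kfac.synthetic_data import (
    ChipTruth,
    ICECHIP_STANDARDS,
    SimParams,
    default_chip_truth,
    simulate_cells,
    simulate_expression_events,
    simulate_icechip,
)


def poised_params(**kw):
    base = dict(n_cells=30, seed=5, base_error_rate=0.0,
                state_probabilities={"poised": 1.0})
    base.update(kw)
    return SimParams(**base)


class TestCellGenerator:
    def test_rerun_is_byte_identical(self, model, tmp_path):
        for sub in ("a", "b"):
            simulate_cells(model, SimParams(n_cells=6, seed=9), out_dir=str(tmp_path / sub))
        for name in ("cell0000.sam", "cell0005.sam", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_different_seeds_differ(self, model):
        a = simulate_cells(model, SimParams(n_cells=4, seed=1))
        b = simulate_cells(model, SimParams(n_cells=4, seed=2))
        assert [t.state for t, _ in a] != [t.state for t, _ in b] or \
               [len(x) for _, x in a] != [len(x) for _, x in b]

    def test_forced_state_probabilities(self, model):
        cohort = simulate_cells(model, poised_params())
        assert all(t.state == "poised" for t, _ in cohort)
        assert all(t.jk_germline == "biallelic" for t, _ in cohort)

    def test_error_free_reads_match_one_haplotype(self, model):
        """With zero error rate every read is an exact haplotype substring."""
        haps = None
        for truth, aln in simulate_cells(model, poised_params(n_cells=8)):
            haps = haps or {a: model.reference_sequences[a] for a in ("B6", "CAST")}
            for read in aln.reads:
                matched = False
                for hap in haps.values():
                    q = 0
                    ok = True
                    for (s0, s1) in read.ref_blocks():
                        n = s1 - s0
                        if read.seq[q:q + n] != hap[s0:s1]:
                            ok = False
                            break
                        q += n
                    matched = matched or ok
                assert matched, f"read {read.name} matches neither haplotype"

    def test_snp_bases_follow_unit_allele(self, model):
        """Reads over a unit's segments carry the planted allele's SNP bases."""
        for truth, aln in simulate_cells(model, poised_params(n_cells=10)):
            for unit in truth.transcription_units:
                for seg_id in unit.segment_ids:
                    seg = model.segment(seg_id)
                    for snp in model.snps_in(seg.start, seg.end):
                        want = snp.b6_base if unit.allele == "B6" else snp.cast_base
                        for read in aln.fetch(snp.position, snp.position + 1):
                            base = read.base_at(snp.position)
                            if base is not None:
                                assert base == want

    def test_units_confined_to_their_tad(self, model):
        for truth, _ in simulate_cells(model, poised_params(n_cells=40, seed=6)):
            for unit in truth.transcription_units:
                segs = [model.segment(i) for i in unit.segment_ids]
                lo, hi = min(s.start for s in segs), max(s.end for s in segs)
                assert model.tad_of(lo) == model.tad_of(hi - 1) == unit.tad

    def test_planted_junctions_are_canonical_gt_ag(self, model):
        seq = model.reference_sequences["B6"]
        n = 0
        for truth, aln in simulate_cells(model, poised_params(n_cells=15, antisense_fraction=0.5)):
            for j in extract_junctions(aln):
                left, right, canonical = junction_motifs(j, seq)
                assert canonical, (left, right)
                n += 1
        assert n > 50

    def test_same_allele_fraction_recovers_parameter(self, model):
        p = 0.7
        cohort = simulate_cells(model, poised_params(n_cells=400, seed=8,
                                                     p_same_allele_locuswide=p))
        frac = np.mean([t.same_allele_locuswide for t, _ in cohort])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 400)
        # the complement is guaranteed non-locuswide, never ambiguous
        for t, _ in cohort:
            if not t.same_allele_locuswide:
                assert len(set(t.chosen_allele_per_tad.values())) == 2

    def test_depth_zero_with_poised_cells_errors(self, model):
        with pytest.raises(ValueError, match="depth"):
            simulate_cells(model, poised_params(depth=0.0))

    def test_bad_state_probabilities_error(self, model):
        with pytest.raises(ValueError):
            simulate_cells(model, SimParams(state_probabilities={"poised": 0.5}))

    def test_sam_round_trip_preserves_reads(self, model, tmp_path):
        truth, aln = simulate_cells(model, poised_params(n_cells=1))[0]
        path = tmp_path / "cell.sam"
        aln.to_sam(str(path))
        again = CellAlignmentSet.from_sam(str(path), cell_id=aln.cell_id)
        assert len(again) == len(aln)
        for a, b in zip(aln.reads, again.reads):
            assert (a.name, a.start, a.cigar, a.seq, a.mapq) == \
                   (b.name, b.start, b.cigar, b.seq, b.mapq)


class TestEventGenerator:
    def test_uniform_null_hits_all_segments(self, model, rng):
        events = simulate_expression_events(model, 500, rng=rng)
        segs = {s for _, s in events}
        assert segs == {s.id for s in model.vk_segments}

    def test_events_unique_per_cell(self, model, rng):
        events = simulate_expression_events(model, 100, rng=rng)
        assert len(events) == len(set(events))

    def test_e2a_odds_shift_event_mass(self, model, rng):
        e2a = {s.id for s in model.vk_segments if s.e2a_bound}
        null = simulate_expression_events(model, 800, e2a_odds=1.0, rng=rng)
        biased = simulate_expression_events(model, 800, e2a_odds=6.0, rng=rng)
        frac = lambda ev: np.mean([s in e2a for _, s in ev])
        assert frac(biased) > frac(null) + 0.1


class TestIceChipGenerator:
    def test_noise_free_closed_form(self, model):
        truth = default_chip_truth(model)
        data = simulate_icechip(model, truth, depth=20, noise="none")
        assert np.array_equal(data.input_coverage, np.full(model.length, 20.0))
        assert np.allclose(data.ip_coverage, 20 * truth.planted_hmd)
        assert data.ip_barcodes["H3K27me3"] == truth.barcode_counts_input["H3K27me3"]

    def test_zero_capture_standard_gets_zero_ip_barcodes(self, model):
        truth = default_chip_truth(model)
        truth.standard_capture["H3K9me3"] = 0.0
        for noise in ("none", "poisson"):
            data = simulate_icechip(model, truth, depth=10, seed=3, noise=noise)
            assert data.ip_barcodes["H3K9me3"] == 0.0

    def test_two_seeds_same_expectation_within_3se(self, model):
        truth = ChipTruth(
            planted_hmd=np.full(model.length, 0.3),
            standard_capture={s: (1.0 if s == "H3K27me3" else 0.05) for s in ICECHIP_STANDARDS},
            barcode_counts_input={s: 10_000 for s in ICECHIP_STANDARDS})
        realizations = []
        for seed in (1, 2):
            data = simulate_icechip(model, truth, depth=30, seed=seed)
            realizations.append(data)
            for std, capture in truth.standard_capture.items():
                expected = 10_000 * capture
                se = np.sqrt(expected)
                assert abs(data.ip_barcodes[std] - expected) <= 3 * se
        assert not np.array_equal(realizations[0].ip_coverage, realizations[1].ip_coverage)

    def test_invalid_inputs_rejected(self, model):
        truth = default_chip_truth(model)
        with pytest.raises(ValueError):
            simulate_icechip(model, truth, depth=0)
        truth.planted_hmd = truth.planted_hmd + 2.0
        with pytest.raises(ValueError):
            simulate_icechip(model, truth, depth=10)
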