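"""ICeChIP: filters, enrichment, specificity, HMD, metagene binning."""

import numpy as np
import pytest

from kfac.alignments import Read
from kfac.icechip_hmd import (
    BarcodeTable,
    barcode_enrichment,
    filter_fragments,
    fragments_to_coverage,
    hmd_track,
    metagene,
    read_bedgraph,
    region_hmd,
    specificity,
    tss_window,
    write_bedgraph,
)

PAIRED_PROPER = 0x1 | 0x2


def _pair(name, start, frag_len, mapq=(60, 60), flag=PAIRED_PROPER):
    """A proper read pair flattening to a fragment of ``frag_len``."""
    r1 = Read(name, start, (("M", 50),), "A" * 50, mapq=mapq[0], flag=flag)
    r2 = Read(name, start + frag_len - 50, (("M", 50),), "A" * 50, mapq=mapq[1], flag=flag | 0x80)
    return [r1, r2]


class TestFragmentFilters:
    def test_length_boundary(self):
        reads = _pair("a", 100, 219) + _pair("b", 100, 220) + _pair("c", 100, 221)
        frags = filter_fragments(reads)
        assert [e - s for s, e in frags] == [219, 220]

    def test_low_mapq_mate_drops_pair(self):
        reads = _pair("lo", 100, 200, mapq=(19, 60)) + _pair("at", 500, 200, mapq=(20, 60))
        assert filter_fragments(reads) == [(500, 700)]

    def test_unpaired_and_improper_dropped(self):
        unpaired = Read("u", 100, (("M", 50),), "A" * 50, flag=0)
        improper = _pair("i", 100, 200, flag=0x1)  # paired but not proper
        mate_unmapped = _pair("m", 100, 200, flag=PAIRED_PROPER | 0x8)
        assert filter_fragments([unpaired] + improper + mate_unmapped) == []

    def test_filter_order_independence(self):
        """MAPQ-then-length equals length-then-MAPQ (the composite filter)."""
        reads = []
        for i, (ln, mq) in enumerate([(219, 19), (219, 20), (221, 60), (150, 60), (220, 19)]):
            reads += _pair(f"p{i}", 1000 * i, ln, mapq=(mq, 60))
        by_mapq = [r for r in reads if r.mapq >= 20]
        frags_a = [(s, e) for s, e in filter_fragments(by_mapq)]
        frags_b = filter_fragments(reads)
        assert frags_a == frags_b == [(1000, 1219), (3000, 3150)]

    def test_fragments_to_coverage(self):
        cov = fragments_to_coverage([(2, 5), (3, 8)], 10)
        assert list(cov) == [0, 0, 1, 2, 2, 1, 1, 1, 0, 0]


class TestBarcodes:
    def test_enrichment_ratio(self):
        table = BarcodeTable(ip={"t": 200.0, "z": 0.0}, input={"t": 100.0, "z": 50.0}, target="t")
        enr, target = barcode_enrichment(table)
        assert target == 2.0 and enr["z"] == 0.0

    def test_zero_input_flagged_undefined(self):
        table = BarcodeTable(ip={"t": 10.0, "u": 5.0}, input={"t": 10.0, "u": 0.0}, target="t")
        enr, _ = barcode_enrichment(table)
        assert enr["u"] is None
        spec = specificity(enr, "t")
        assert "u" not in spec

    def test_missing_target_input_errors(self):
        with pytest.raises(ValueError):
            barcode_enrichment(BarcodeTable(ip={"t": 1.0}, input={"t": 0.0}, target="t"))

    def test_specificity_modes(self):
        enr = {"t": 4.0, "off": 0.2}
        assert specificity(enr, "t") == {"t": 1.0, "off": pytest.approx(0.05)}
        s = specificity({"a": 2.0, "b": 2.0, "c": 2.0}, "a")
        assert set(s.values()) == {1.0}
        s_sum = specificity(enr, "t", mode="sum")
        assert s_sum["t"] == pytest.approx(4.0 / 4.2)


class TestHMD:
    def test_formula_identities(self):
        track = hmd_track(np.array([30.0, 15.0, 5.0]), np.array([10.0, 10.0, 0.0]), 3.0)
        assert track.hmd[0] == pytest.approx(100.0)
        assert track.hmd[1] == pytest.approx(50.0)
        assert np.isnan(track.hmd[2]) and not track.defined[2]

    def test_depth_rescaling_invariance(self, rng):
        """Scaling IP coverage and IP barcode counts by k leaves HMD unchanged."""
        ip = rng.poisson(20, size=500).astype(float)
        inp = rng.poisson(30, size=500).astype(float)
        table = BarcodeTable(ip={"t": 4000.0}, input={"t": 1000.0}, target="t")
        _, enr = barcode_enrichment(table)
        base = hmd_track(ip, inp, enr)
        k = 7.5
        scaled_table = BarcodeTable(ip={"t": 4000.0 * k}, input={"t": 1000.0}, target="t")
        _, enr_k = barcode_enrichment(scaled_table)
        scaled = hmd_track(ip * k, inp, enr_k)
        assert np.allclose(base.hmd, scaled.hmd, equal_nan=True)

    def test_region_hmd_is_ratio_of_means(self):
        track = hmd_track(np.array([10.0, 30.0]), np.array([10.0, 10.0]), 2.0)
        assert region_hmd(track, 0, 2) == pytest.approx(100.0)

    def test_nonpositive_enrichment_rejected(self):
        with pytest.raises(ValueError):
            hmd_track(np.ones(3), np.ones(3), 0.0)


class TestMetagene:
    def test_constant_track_gives_flat_profile(self):
        vals = np.full(2000, 3.5)
        prof = metagene(vals, [(200, 700, "+"), (900, 1100, "-")])
        assert prof.bins.shape == (100,)
        assert np.allclose(prof.bins, 3.5)

    def test_length_invariance_of_percentage_bins(self):
        """Two genes of different lengths with constant tracks c1, c2 -> (c1+c2)/2."""
        vals = np.zeros(3000)
        vals[100:400] = 2.0
        vals[1000:2200] = 6.0
        prof = metagene(vals, [(130, 370, "+"), (1150, 2050, "+")])
        assert np.allclose(prof.bins, 4.0)

    def test_linearity_over_gene_sets(self, rng):
        vals = rng.random(5000)
        g1, g2 = (300, 800, "+"), (2000, 2600, "-")
        both = metagene(vals, [g1, g2]).bins
        single = (metagene(vals, [g1]).bins + metagene(vals, [g2]).bins) / 2
        assert np.allclose(both, single)

    def test_step_track_matches_overlap_weighted_oracle(self):
        vals = np.zeros(1000)
        vals[200:300] = 10.0
        prof = metagene(vals, [(100, 300, "+")]).bins
        edges = np.linspace(80, 320, 101)
        oracle = np.array([
            10 * max(0.0, min(edges[i + 1], 300) - max(edges[i], 200)) / (edges[i + 1] - edges[i])
            for i in range(100)])
        assert np.allclose(prof, oracle)

    def test_strand_reversal_symmetry(self, rng):
        vals = rng.random(2000)
        plus = metagene(vals, [(500, 900, "+")]).bins
        minus = metagene(vals, [(500, 900, "-")]).bins
        assert np.allclose(plus, minus[::-1])

    def test_gene_outside_track_excluded(self):
        vals = np.ones(1000)
        prof = metagene(vals, [(100, 300, "+", "in"), (950, 999, "+", "out")])
        assert prof.n_genes == 1 and prof.excluded == ["out"]
        with pytest.raises(ValueError):
            metagene(vals, [(950, 999, "+")])

    def test_nan_positions_excluded_from_bin_means(self):
        vals = np.full(1000, 5.0)
        vals[250:260] = np.nan
        prof = metagene(vals, [(100, 300, "+")]).bins
        assert np.allclose(prof[np.isfinite(prof)], 5.0)


class TestTSSWindow:
    def test_constant_track(self):
        assert tss_window(np.full(500, 2.0), [(100, 300, "+")]) == pytest.approx(2.0)

    def test_signal_in_second_half_of_body_is_zero(self):
        vals = np.zeros(1000)
        vals[200:300] = 8.0
        assert tss_window(vals, [(100, 300, "+")]) == 0.0

    def test_promoter_peak_exceeds_body_mean(self):
        vals = np.zeros(1000)
        vals[90:130] = 9.0  # peak straddling the TSS at 100
        genes = [(100, 300, "+")]
        assert tss_window(vals, genes) > np.mean(vals[100:300])

    def test_minus_strand_window_at_gene_end(self):
        vals = np.zeros(1000)
        vals[280:320] = 4.0
        assert tss_window(vals, [(100, 300, "-")]) > 0
        assert tss_window(vals, [(100, 300, "+")]) == 0.0


class TestBedgraphIO:
    def test_round_trip_with_nan_gaps(self, tmp_path, rng):
        vals = np.repeat(rng.random(20).round(6), 50)
        vals[100:150] = np.nan
        path = str(tmp_path / "t.bedgraph")
        write_bedgraph(vals, "chr", path)
        again = read_bedgraph(path, len(vals))
        assert np.allclose(vals, again, equal_nan=True)
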