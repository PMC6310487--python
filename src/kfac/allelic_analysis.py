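"""SNP-based allele-of-origin calls and monoallelism summaries.

For each expressed segment the bases over its B6/CAST SNPs are pooled across
qualifying SNPs (total coverage of at least 30 per SNP, following the study's
allelic-assignment threshold) and the segment is called B6, CAST, biallelic,
or insufficient.  A segment is single-allele when the minor haplotype carries
at most ``minor_fraction_max`` (default 10%) of the pooled SNP bases, a
tolerance absorbing sequencing error.

Monoallelism is summarised three ways over poised cells, mirroring the study:
per expression event (cell x gene), locus-wide (all of a cell's expressed
V-kappas on one allele), and over the nine most highly used V-kappa genes.
The fraction of cells with biallelic germline J-kappa is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from kfac.alignments import CellAlignmentSet
from kfac.locus_model import HaplotypeSNP, LocusModel, Segment

COVERAGE_THRESHOLD = 30  # minimum reads per SNP for allelic assignment


@dataclass
class AlleleCall:
    cell_id: str
    segment_id: str
    allele: str  # B6 / CAST / biallelic / insufficient
    snp_coverage: dict[int, tuple[int, int]] = field(default_factory=dict)  # pos -> (b6, cast)
    reason: str | None = None

    @property
    def informative(self) -> bool:
        return self.allele != "insufficient"

    @property
    def single_allele(self) -> bool:
        return self.allele in ("B6", "CAST")


@dataclass
class MonoallelismSummary:
    per_gene_fraction: float
    locuswide_fraction: float
    hu_fraction: float
    jk_biallelic_fraction: float
    n_events: int
    n_cells_locuswide: int
    n_cells_hu: int
    n_cells_jk: int


def call_segment_allele(alignments, segment: Segment, snps: list[HaplotypeSNP],
                        coverage_threshold: int = COVERAGE_THRESHOLD,
                        minor_fraction_max: float = 0.1,
                        cell_id: str | None = None) -> AlleleCall:
    """Call a segment's allele of origin from the reads covering its SNPs.

    ``alignments`` may be a :class:`CellAlignmentSet` or a pre-fetched list of
    reads overlapping the segment.  SNPs qualify when their total haplotype-
    matching coverage reaches ``coverage_threshold``; qualifying SNPs are
    pooled.  With no SNP or none qualifying the call is ``insufficient``.
    """
    if isinstance(alignments, CellAlignmentSet):
        cell_id = cell_id or alignments.cell_id
        reads = alignments.fetch(segment.start, segment.end)
    else:
        reads = alignments
    cell_id = cell_id or ""
    if not snps:
        return AlleleCall(cell_id, segment.id, "insufficient", reason="no_snps")

    coverage: dict[int, tuple[int, int]] = {}
    for snp in snps:
        b6 = cast = 0
        for read in reads:
            base = read.base_at(snp.position)
            if base == snp.b6_base:
                b6 += 1
            elif base == snp.cast_base:
                cast += 1
        coverage[snp.position] = (b6, cast)

    pooled_b6 = pooled_cast = 0
    for b6, cast in coverage.values():
        if b6 + cast >= coverage_threshold:
            pooled_b6 += b6
            pooled_cast += cast
    if pooled_b6 + pooled_cast == 0:
        return AlleleCall(cell_id, segment.id, "insufficient", coverage, reason="coverage")
    cast_fraction = pooled_cast / (pooled_b6 + pooled_cast)
    if cast_fraction <= minor_fraction_max:
        allele = "B6"
    elif cast_fraction >= 1.0 - minor_fraction_max:
        allele = "CAST"
    else:
        allele = "biallelic"
    return AlleleCall(cell_id, segment.id, allele, coverage)


def call_cell_alleles(alignments: CellAlignmentSet, model: LocusModel,
                      expression_min_reads: int = 5,
                      coverage_threshold: int = COVERAGE_THRESHOLD,
                      minor_fraction_max: float = 0.1) -> list[AlleleCall]:
    """Allele calls for every expressed V-kappa and J-kappa segment of one cell.

    A segment is expressed when at least ``expression_min_reads`` read blocks
    overlap it.
    """
    buckets: dict[str, list] = {}
    for read in alignments.reads:
        seen = set()
        for s0, s1 in read.ref_blocks():
            for seg in model.segments_overlapping(s0, s1):
                if (seg.is_vk or seg.klass == "Jk") and seg.id not in seen:
                    seen.add(seg.id)
                    buckets.setdefault(seg.id, []).append(read)
    calls = []
    for seg_id, reads in sorted(buckets.items()):
        if len(reads) < expression_min_reads:
            continue
        seg = model.segment(seg_id)
        calls.append(call_segment_allele(
            reads, seg, model.snps_in(seg.start, seg.end),
            coverage_threshold=coverage_threshold,
            minor_fraction_max=minor_fraction_max, cell_id=alignments.cell_id))
    return calls


def summarize_monoallelism(calls: list[AlleleCall], model: LocusModel,
                           include_single_gene_cells: bool = True) -> MonoallelismSummary:
    """Monoallelism fractions over a poised-cell cohort's allele calls.

    Cells contribute to each denominator only where they have informative
    calls; ``include_single_gene_cells=False`` restricts the locus-wide
    fraction to cells with at least two informative V-kappa calls.
    """
    if not calls:
        raise ValueError("no allele calls provided")
    hu_ids = {s.id for s in model.highly_used}
    vk_ids = {s.id for s in model.vk_segments}
    jk_ids = {s.id for s in model.jk_segments}

    by_cell: dict[str, list[AlleleCall]] = {}
    for call in calls:
        by_cell.setdefault(call.cell_id, []).append(call)

    n_events = n_single = 0
    n_cells_lw = n_mono_lw = 0
    n_cells_hu = n_mono_hu = 0
    n_cells_jk = n_bi_jk = 0
    for cell_calls in by_cell.values():
        vk = [c for c in cell_calls if c.segment_id in vk_ids and c.informative]
        n_events += len(vk)
        n_single += sum(c.single_allele for c in vk)
        min_genes = 1 if include_single_gene_cells else 2
        if len(vk) >= min_genes:
            n_cells_lw += 1
            alleles = {c.allele for c in vk}
            if alleles in ({"B6"}, {"CAST"}):
                n_mono_lw += 1
        hu = [c for c in vk if c.segment_id in hu_ids]
        if hu:
            n_cells_hu += 1
            alleles = {c.allele for c in hu}
            if alleles in ({"B6"}, {"CAST"}):
                n_mono_hu += 1
        jk = [c for c in cell_calls if c.segment_id in jk_ids and c.informative]
        if jk:
            n_cells_jk += 1
            alleles = {c.allele for c in jk}
            if "biallelic" in alleles or {"B6", "CAST"} <= alleles:
                n_bi_jk += 1

    return MonoallelismSummary(
        per_gene_fraction=n_single / n_events if n_events else float("nan"),
        locuswide_fraction=n_mono_lw / n_cells_lw if n_cells_lw else float("nan"),
        hu_fraction=n_mono_hu / n_cells_hu if n_cells_hu else float("nan"),
        jk_biallelic_fraction=n_bi_jk / n_cells_jk if n_cells_jk else float("nan"),
        n_events=n_events, n_cells_locuswide=n_cells_lw,
        n_cells_hu=n_cells_hu, n_cells_jk=n_cells_jk)


def calls_to_frame(calls: list[AlleleCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": c.cell_id, "segment": c.segment_id, "allele": c.allele,
        "b6_reads": sum(v[0] for v in c.snp_coverage.values()),
        "cast_reads": sum(v[1] for v in c.snp_coverage.values()),
    } for c in calls])
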