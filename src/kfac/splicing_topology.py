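"""Splice-graph extraction, interpolation and transcription-unit inference.

Splice junctions come from the N operations of read CIGAR strings: a read
aligned at p whose CIGAR consumes m reference bases before an N gap of length
L yields the genomic junction [p+m, p+m+L).  Junction edges are aggregated per
(donor segment, acceptor segment) and only edges supported by at least
``min_count`` reads (default 10, the study's reporting threshold) are kept.

Junction strand is inferred from the genomic dinucleotides at the junction's
interior edges: GT..AG marks a plus-strand transcript, CT..AC a minus-strand
one (GT..AG after reverse complement).

Because read-through transcription covers every gene it passes, all annotated
V-kappa segments lying strictly between two spliced segments are interpolated
as transcribed.  Transcription units are the connected components of the
splice graph (kept separate per transcript strand) augmented with the
interpolated segments; an edge joining segments in different TADs is flagged
as an anomaly and excluded from units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from kfac.alignments import CellAlignmentSet
from kfac.locus_model import LocusModel

MIN_JUNCTION_COUNT = 10


@dataclass
class SpliceJunction:
    """A splice junction, normalised to genomic order (donor_pos < acceptor_pos).

    ``donor_*`` / ``acceptor_*`` name the genomic left / right edge; for a
    minus-strand transcript the biological donor is the right edge.
    """

    cell_id: str
    donor_pos: int
    acceptor_pos: int
    count: int = 1
    strand: str | None = None
    donor_segment: str | None = None
    acceptor_segment: str | None = None
    donor_dinuc: str | None = None
    acceptor_dinuc: str | None = None
    canonical: bool | None = None


@dataclass
class SpliceGraph:
    cell_id: str
    nodes: set = field(default_factory=set)
    edges: dict = field(default_factory=dict)  # (donor_seg, acceptor_seg, strand) -> SpliceJunction
    dropped: list = field(default_factory=list)  # edges below min_count
    intergenic: list = field(default_factory=list)  # junctions not at annotated segments


@dataclass
class TranscriptionUnit:
    cell_id: str
    segment_ids: list[str]  # genomic order
    span: int
    tad: str | None
    strand: str | None
    n_interpolated: int = 0
    exonic_length: int = 0


def extract_junctions(alignments: CellAlignmentSet) -> list[SpliceJunction]:
    """Per-read junctions (pre-aggregation); one entry per N gap per read."""
    out = []
    cell = alignments.cell_id
    for read in alignments.reads:
        for d, a in read.junctions():
            out.append(SpliceJunction(cell_id=cell, donor_pos=d, acceptor_pos=a))
    return out


def junction_motifs(junction: SpliceJunction, sequence: str) -> tuple[str, str, bool]:
    """Genomic dinucleotides at the junction's interior edges and canonicity.

    Canonical means GT..AG on the transcript strand, i.e. GT..AG (plus) or
    CT..AC (minus) on the reference.
    """
    d, a = junction.donor_pos, junction.acceptor_pos
    if d < 2 or a > len(sequence):
        raise ValueError(f"junction ({d}, {a}) outside sequence")
    left = sequence[d:d + 2]
    right = sequence[a - 2:a]
    canonical = (left, right) in (("GT", "AG"), ("CT", "AC"))
    return left, right, canonical


def _junction_strand(left: str, right: str) -> str | None:
    if (left, right) == ("GT", "AG"):
        return "+"
    if (left, right) == ("CT", "AC"):
        return "-"
    return None


def aggregate_and_filter(junctions: list[SpliceJunction], model: LocusModel,
                         min_count: int = MIN_JUNCTION_COUNT, slack: int = 8) -> SpliceGraph:
    """Aggregate raw junctions into segment-to-segment edges and apply the
    minimum-observation filter; sub-threshold edges are kept in ``dropped``."""
    cell = junctions[0].cell_id if junctions else ""
    graph = SpliceGraph(cell_id=cell)
    by_coord: dict[tuple[int, int], int] = {}
    for j in junctions:
        key = (j.donor_pos, j.acceptor_pos)
        by_coord[key] = by_coord.get(key, 0) + j.count
    seq = model.reference_sequences["B6"]  # motif positions are haplotype-invariant

    by_edge: dict[tuple, SpliceJunction] = {}
    for (d, a), n in sorted(by_coord.items()):
        left_seg = model.segment_at(d - 1, slack=slack)
        right_seg = model.segment_at(a, slack=slack)
        dinuc_l, dinuc_r, canonical = junction_motifs(SpliceJunction(cell, d, a), seq)
        strand = _junction_strand(dinuc_l, dinuc_r)
        j = SpliceJunction(
            cell_id=cell, donor_pos=d, acceptor_pos=a, count=n, strand=strand,
            donor_segment=left_seg.id if left_seg else None,
            acceptor_segment=right_seg.id if right_seg else None,
            donor_dinuc=dinuc_l, acceptor_dinuc=dinuc_r, canonical=canonical)
        if left_seg is None or right_seg is None:
            graph.intergenic.append(j)
            continue
        key = (left_seg.id, right_seg.id, strand)
        if key in by_edge:
            by_edge[key].count += n
        else:
            by_edge[key] = j
    for key, j in by_edge.items():
        if j.count >= min_count:
            graph.edges[key] = j
            graph.nodes.update(key[:2])
        else:
            graph.dropped.append(j)
    return graph


def interpolate_transcribed(graph: SpliceGraph, model: LocusModel) -> tuple[set, list]:
    """Observed plus interpolated segment ids, and the flagged cross-TAD edges.

    For every within-TAD edge (A, B), every annotated V-kappa segment lying
    strictly between A and B is added as interpolated.  Edges whose endpoints
    sit in different TADs are anomalies: flagged and excluded.
    """
    transcribed = set(graph.nodes)
    anomalies = []
    for (left_id, right_id, _strand), edge in graph.edges.items():
        left, right = model.segment(left_id), model.segment(right_id)
        if not (left.is_vk and right.is_vk):
            continue
        if model.tad_of(left.start) != model.tad_of(right.start):
            anomalies.append(edge)
            continue
        for seg in model.vk_segments:
            if seg.start >= left.end and seg.end <= right.start:
                transcribed.add(seg.id)
    return transcribed, anomalies


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def infer_units(graph: SpliceGraph, model: LocusModel,
                observed_segments: set | None = None) -> tuple[list[TranscriptionUnit], list]:
    """Transcription units: connected splice-graph components plus interpolated
    segments, kept separate per strand; segments expressed without junctions
    (``observed_segments``) become singleton units.

    Returns (units, anomalous cross-TAD edges).
    """
    transcribed, anomalies = interpolate_transcribed(graph, model)
    anomalous = {(e.donor_segment, e.acceptor_segment, e.strand) for e in anomalies}
    uf = _UnionFind()
    observed = set(graph.nodes) | (observed_segments or set())
    for (left_id, right_id, strand), edge in graph.edges.items():
        left, right = model.segment(left_id), model.segment(right_id)
        if not (left.is_vk and right.is_vk):
            continue
        if (left_id, right_id, strand) in anomalous:
            continue
        uf.union((left_id, strand), (right_id, strand))
        for seg in model.vk_segments:
            if seg.start >= left.end and seg.end <= right.start:
                uf.union((seg.id, strand), (left_id, strand))

    components: dict = {}
    for node in list(uf.parent):
        components.setdefault(uf.find(node), set()).add(node)

    units = []
    in_component = {seg_id for comp in components.values() for seg_id, _ in comp}
    for comp in components.values():
        seg_ids = sorted({s for s, _ in comp}, key=lambda i: model.segment(i).start)
        strand = next(iter({st for _, st in comp}))
        units.append(_make_unit(graph.cell_id, seg_ids, strand, model, observed))
    for seg_id in sorted((observed_segments or set()) - in_component):
        seg = model.segment(seg_id)
        if seg.is_vk:
            units.append(_make_unit(graph.cell_id, [seg_id], seg.orientation, model, observed))
    units.sort(key=lambda u: model.segment(u.segment_ids[0]).start)
    return units, anomalies


def _make_unit(cell_id, seg_ids, strand, model, observed) -> TranscriptionUnit:
    segs = [model.segment(i) for i in seg_ids]
    return TranscriptionUnit(
        cell_id=cell_id, segment_ids=seg_ids,
        span=segs[-1].end - segs[0].start,
        tad=model.tad_of(segs[0].start), strand=strand,
        n_interpolated=sum(1 for i in seg_ids if i not in observed),
        exonic_length=sum(s.end - s.start for s in segs))


def analyze_cell(alignments: CellAlignmentSet, model: LocusModel,
                 min_count: int = MIN_JUNCTION_COUNT,
                 expression_min_reads: int = 5):
    """Full per-cell splicing pipeline: junctions -> graph -> units.

    Returns (graph, units, anomalies).  Expressed V-kappa segments without
    junction support enter as singleton units.
    """
    graph = aggregate_and_filter(extract_junctions(alignments), model, min_count=min_count)
    observed = set()
    counts: dict[str, int] = {}
    for read in alignments.reads:
        seen = set()
        for s0, s1 in read.ref_blocks():
            for seg in model.segments_overlapping(s0, s1):
                if seg.is_vk and seg.id not in seen:
                    seen.add(seg.id)
                    counts[seg.id] = counts.get(seg.id, 0) + 1
    observed = {i for i, n in counts.items() if n >= expression_min_reads}
    units, anomalies = infer_units(graph, model, observed_segments=observed)
    return graph, units, anomalies


def unit_stats(units: list[TranscriptionUnit]) -> dict:
    if not units:
        return {"n_units": 0, "n_segments": 0, "max_span": 0, "mean_span": float("nan")}
    spans = [u.span for u in units]
    return {"n_units": len(units),
            "n_segments": sum(len(u.segment_ids) for u in units),
            "max_span": max(spans),
            "mean_span": sum(spans) / len(spans)}


def units_to_frame(units: list[TranscriptionUnit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": u.cell_id, "tad": u.tad, "strand": u.strand,
        "n_segments": len(u.segment_ids), "n_interpolated": u.n_interpolated,
        "span": u.span, "exonic_length": u.exonic_length,
        "segments": ",".join(u.segment_ids),
    } for u in units])
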