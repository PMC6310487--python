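"""Cell-state classification from alignment evidence.

Each cell is assigned exactly one label:

* ``no_expression`` — no reads over V-kappa/J-kappa segments or the J-kappa
  germline promoters;
* ``recomb_one_allele`` — V-to-J junction reads on exactly one allele;
* ``recomb_two_or_lambda`` — junction reads on both alleles, or junctions
  together with Ig-lambda expression;
* ``poised`` — biallelic germline J-kappa expression (reads assigned to both
  haplotypes from either promoter's transcript), intact RSS motifs in the
  J-segment reads, and zero recombination junctions;
* ``uncategorized`` — everything else (e.g. monoallelic germline J-kappa, or
  junctions whose allele cannot be assigned).

Recombination products are recognised as split reads whose two blocks land in
a V-kappa segment and a J-kappa segment; split reads joining two V-kappa
segments are splicing, not recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from kfac.alignments import CellAlignmentSet, Read
from kfac.locus_model import LocusModel, RSS_HEPTAMER, RSS_NONAMER

LABELS = ("no_expression", "poised", "recomb_one_allele", "recomb_two_or_lambda", "uncategorized")


@dataclass
class JunctionEvidence:
    """One recombination junction (V segment joined to J segment)."""

    allele: str          # B6 / CAST / unassigned
    v_segment: str
    j_segment: str
    count: int


@dataclass
class CellCategory:
    cell_id: str
    label: str
    evidence: dict = field(default_factory=dict)


def read_allele(read: Read, model: LocusModel) -> str:
    """Assign a read to a haplotype from the SNP bases it covers."""
    b6 = cast = 0
    for s0, s1 in read.ref_blocks():
        for snp in model.snps_in(s0, s1):
            base = read.base_at(snp.position)
            if base == snp.b6_base:
                b6 += 1
            elif base == snp.cast_base:
                cast += 1
    if b6 > cast:
        return "B6"
    if cast > b6:
        return "CAST"
    return "unassigned"


def detect_recombination(alignments: CellAlignmentSet, model: LocusModel,
                         slack: int = 8) -> list[JunctionEvidence]:
    """All split-read junctions fusing a V-kappa coding end to a J-kappa segment.

    The junction's allele comes from the SNP bases covered by the read's
    aligned blocks; junctions are aggregated by (V, J, allele).
    """
    counts: dict[tuple[str, str, str], int] = {}
    for read in alignments.reads:
        for d, a in read.junctions():
            left = model.segment_at(d - 1, slack=slack)
            right = model.segment_at(a, slack=slack)
            if left is None or right is None:
                continue
            if left.is_vk and right.klass == "Jk":
                key = (left.id, right.id, read_allele(read, model))
                counts[key] = counts.get(key, 0) + 1
    return [JunctionEvidence(allele=al, v_segment=v, j_segment=j, count=n)
            for (v, j, al), n in sorted(counts.items())]


def _hamming_contains(seq: str, motif: str, max_mismatch: int) -> bool:
    m = len(motif)
    for i in range(len(seq) - m + 1):
        mism = 0
        for a, b in zip(seq[i:i + m], motif):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return True
    return False


def detect_rss_motifs(alignments: CellAlignmentSet, model: LocusModel,
                      heptamer: str = RSS_HEPTAMER, nonamer: str = RSS_NONAMER,
                      max_mismatch: int = 1, flank: int = 45) -> dict[str, bool]:
    """Per J-kappa segment: does any read over its 5' flank carry both RSS motifs?

    Absence of covering reads counts as False (absence of evidence).
    """
    if len(heptamer) != 7 or len(nonamer) != 9:
        raise ValueError("RSS heptamer must be 7 bp and nonamer 9 bp")
    out = {}
    for jk in model.jk_segments:
        found = False
        for read in alignments.fetch(jk.start - flank, jk.start):
            if (_hamming_contains(read.seq, heptamer, max_mismatch)
                    and _hamming_contains(read.seq, nonamer, max_mismatch)):
                found = True
                break
        out[jk.id] = found
    return out


def _germline_jk_counts(alignments: CellAlignmentSet, model: LocusModel) -> dict:
    """Allele-resolved germline J-kappa read counts (junction-free reads only)."""
    jks = model.jk_segments
    promoters = sorted(model.jk_promoters.items())
    regions = [(p[1][0], p[1][1]) for p in promoters] + [(jks[0].start - 250, jks[-1].end + 60)]
    lo = min(r[0] for r in regions)
    hi = max(r[1] for r in regions)
    counts = {"jk_B6": 0, "jk_CAST": 0, "jk_unassigned": 0}
    for name, _ in promoters:
        counts[f"{name}_B6"] = counts[f"{name}_CAST"] = 0
    for read in alignments.fetch(lo, hi):
        blocks = read.ref_blocks()
        if len(blocks) > 1:  # spliced/junction read; not germline J-kappa evidence
            continue
        s0, s1 = blocks[0]
        if s1 <= lo or s0 >= hi:
            continue
        allele = read_allele(read, model)
        counts[f"jk_{allele}"] += 1
        if allele in ("B6", "CAST"):
            for name, (p0, p1) in promoters:
                if s0 < p1 and s1 > p0:
                    counts[f"{name}_{allele}"] += 1
    return counts


def classify_cell(alignments: CellAlignmentSet, model: LocusModel,
                  min_germline_reads: int = 3, min_junction_reads: int = 1,
                  min_igl_reads: int = 5) -> CellCategory:
    """Assign the cell's state label from its alignment evidence."""
    cell_id = alignments.cell_id

    # any evidence of Vk/Jk transcription (segments or germline Jk promoters)?
    jks = model.jk_segments
    jk_lo = min(min(p[0] for p in model.jk_promoters.values()), jks[0].start) if jks else None
    jk_hi = jks[-1].end + 60 if jks else None
    vk_jk_reads = 0
    igl_reads = 0
    for read in alignments.reads:
        for s0, s1 in read.ref_blocks():
            hit = False
            if jk_lo is not None and s0 < jk_hi and s1 > jk_lo:
                hit = True
            else:
                for seg in model.segments_overlapping(s0, s1):
                    if seg.is_vk or seg.klass == "Jk":
                        hit = True
                    elif seg.klass == "Igl":
                        igl_reads += 1
            if hit:
                vk_jk_reads += 1
                break

    junctions = detect_recombination(alignments, model)
    junction_alleles = {}
    for ev in junctions:
        junction_alleles[ev.allele] = junction_alleles.get(ev.allele, 0) + ev.count
    assigned = {al for al, n in junction_alleles.items()
                if al != "unassigned" and n >= min_junction_reads}
    igl_expressed = igl_reads >= min_igl_reads

    evidence = {"vk_jk_reads": vk_jk_reads, "igl_reads": igl_reads,
                "junction_reads": dict(junction_alleles)}

    if vk_jk_reads == 0:
        return CellCategory(cell_id, "no_expression", evidence)

    if junctions:
        if len(assigned) == 2 or (assigned and igl_expressed):
            return CellCategory(cell_id, "recomb_two_or_lambda", evidence)
        if len(assigned) == 1:
            return CellCategory(cell_id, "recomb_one_allele", evidence)
        return CellCategory(cell_id, "uncategorized", evidence)

    germline = _germline_jk_counts(alignments, model)
    rss = detect_rss_motifs(alignments, model)
    evidence.update(germline)
    evidence["rss"] = rss
    biallelic = (germline["jk_B6"] >= min_germline_reads
                 and germline["jk_CAST"] >= min_germline_reads)
    if biallelic and any(rss.values()):
        return CellCategory(cell_id, "poised", evidence)
    return CellCategory(cell_id, "uncategorized", evidence)


def classify_cohort(cells: list[CellAlignmentSet], model: LocusModel, **kwargs) -> pd.DataFrame:
    rows = []
    for aln in cells:
        cat = classify_cell(aln, model, **kwargs)
        rows.append({"cell_id": cat.cell_id, "label": cat.label,
                     "vk_jk_reads": cat.evidence.get("vk_jk_reads", 0),
                     "igl_reads": cat.evidence.get("igl_reads", 0)})
    return pd.DataFrame(rows)


def confusion_matrix(true_labels: dict[str, str], categories: pd.DataFrame) -> pd.DataFrame:
    df = categories.assign(truth=categories["cell_id"].map(true_labels))
    return pd.crosstab(df["truth"], df["label"])
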