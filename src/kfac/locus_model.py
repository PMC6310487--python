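"""Annotated Igkappa locus coordinate frame.

Everything downstream (allelic assignment, splice-graph topology, bias
statistics) is computed against a :class:`LocusModel`: an ordered list of
gene segments (V-kappa / J-kappa / C-kappa / Ig-lambda / control genes), eight
CTCF-bound sites S1..S8, the three TADs they anchor, a two-haplotype (B6 vs
CAST) SNP table, and the two haplotype reference sequences.

Coordinates are 0-based half-open throughout (BED convention).  TAD membership
at a shared anchor resolves by the half-open rule: the anchor position belongs
to the TAD on its right.

The packaged default locus (:func:`default_locus`) is a desk-scale Igkappa:
40 V-kappa segments over ~300 kb in three TADs (distal/intermediate/proximal,
anchored by S1-S5, S5-S6, S6-S8), four J-kappa segments with their two
germline promoters, one C-kappa, three Ig-lambda segments and four control
genes.  It preserves the structural features the analyses rely on: mixed
transcriptional orientations, the nine most highly used V-kappa gene names,
E2A-preloaded promoters, recombination-signal-sequence (RSS) motifs flanking
the J segments, canonical splice dinucleotides at segment edges, and at least
one high-quality SNP inside every V-kappa and J-kappa segment.
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

# Canonical V(D)J recombination signal sequence consensus motifs.
RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"

VK_CLASSES = ("Vk_distal", "Vk_intermediate", "Vk_proximal")

# Offsets (bp) of planted splice dinucleotides relative to segment edges.
# Sense junctions run [donor_seg.end, acceptor_seg.start) with GT..AG on the
# reference; antisense junctions are inset by ANTISENSE_OFFSET bp on both
# sides and read CT..AC on the reference (GT..AG on the minus strand).
ANTISENSE_OFFSET = 4

SNP_MIN_QUALITY = 100.0


class LocusValidationError(ValueError):
    """Raised when a locus annotation violates a structural invariant."""


@dataclass(frozen=True)
class Segment:
    """One annotated gene segment.

    ``interval`` is [start, end), 0-based.  ``orientation`` is the
    transcriptional direction ('+' or '-').  ``klass`` is one of Vk_distal /
    Vk_intermediate / Vk_proximal / Jk / Ck / Igl / control_gene.
    """

    id: str
    start: int
    end: int
    orientation: str
    klass: str
    functional: bool = True
    highly_used: bool = False
    e2a_bound: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise LocusValidationError(f"segment {self.id}: start >= end")
        if self.orientation not in ("+", "-"):
            raise LocusValidationError(f"segment {self.id}: bad orientation")
        if self.highly_used and self.klass not in VK_CLASSES:
            raise LocusValidationError(f"segment {self.id}: highly_used requires a Vk class")

    @property
    def is_vk(self) -> bool:
        return self.klass in VK_CLASSES

    @property
    def tss(self) -> int:
        """Transcription start position: 5' end in the transcription direction."""
        return self.start if self.orientation == "+" else self.end


@dataclass(frozen=True)
class CTCFSite:
    id: str  # S1..S8
    position: int


@dataclass(frozen=True)
class TAD:
    name: str  # distal / intermediate / proximal
    left_anchor: str
    right_anchor: str
    start: int
    end: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class HaplotypeSNP:
    position: int
    b6_base: str
    cast_base: str
    quality: float

    def __post_init__(self):
        if self.b6_base == self.cast_base:
            raise LocusValidationError(f"SNP at {self.position}: identical alleles")


# (TAD name, left anchor, right anchor) -- the fixed anchoring scheme.
TAD_ANCHORS = (("distal", "S1", "S5"), ("intermediate", "S5", "S6"), ("proximal", "S6", "S8"))


@dataclass
class LocusModel:
    """Validated locus annotation plus the two haplotype sequences."""

    chrom: str
    length: int
    segments: list[Segment]
    ctcf_sites: list[CTCFSite]
    tads: list[TAD]
    snps: list[HaplotypeSNP]
    reference_sequences: dict[str, str]  # {"B6": seq, "CAST": seq}
    jk_promoters: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: s.start)
        self.snps = sorted(self.snps, key=lambda s: s.position)
        self._by_id = {s.id: s for s in self.segments}
        self._starts = [s.start for s in self.segments]
        self._snp_positions = [s.position for s in self.snps]
        self.validate()

    # -- lookups -----------------------------------------------------------

    def segment(self, seg_id: str) -> Segment:
        return self._by_id[seg_id]

    @property
    def vk_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.is_vk]

    @property
    def jk_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.klass == "Jk"]

    @property
    def highly_used(self) -> list[Segment]:
        return [s for s in self.segments if s.highly_used]

    def segments_overlapping(self, start: int, end: int) -> list[Segment]:
        """Segments whose interval intersects [start, end)."""
        # segments are short and non-overlapping; scan a bounded window
        i = bisect_right(self._starts, end) - 1
        out = []
        while i >= 0:
            s = self.segments[i]
            if s.start < start - 10_000:  # all segments are < 10 kb long
                break
            if s.start < end and s.end > start:
                out.append(s)
            i -= 1
        out.reverse()
        return out

    def segment_at(self, position: int, slack: int = 0) -> Segment | None:
        """The segment whose interval (widened by ``slack`` bp) contains ``position``."""
        hits = self.segments_overlapping(position - slack, position + slack + 1)
        return hits[0] if hits else None

    def snps_in(self, start: int, end: int) -> list[HaplotypeSNP]:
        i = bisect_left(self._snp_positions, start)
        j = bisect_left(self._snp_positions, end)
        return self.snps[i:j]

    def tad_of(self, position: int) -> str | None:
        """TAD name containing ``position`` under half-open membership, else None."""
        for tad in self.tads:
            if position in tad:
                return tad.name
        return None

    def tad(self, name: str) -> TAD:
        return next(t for t in self.tads if t.name == name)

    def ctcf(self, site_id: str) -> CTCFSite:
        return next(s for s in self.ctcf_sites if s.id == site_id)

    def nearest_ctcf(self, segment: Segment) -> CTCFSite:
        """CTCF site nearest the segment's TSS; ties resolve to the 5' site."""
        tss = segment.tss
        return min(self.ctcf_sites, key=lambda s: (abs(tss - s.position), s.position))

    def orientation_class(self, segment: Segment) -> str:
        """'away' or 'toward' relative to the nearest CTCF site."""
        _, orient = signed_distance_and_orientation(segment, self.nearest_ctcf(segment))
        return orient

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if not self.segments:
            raise LocusValidationError("no segments")
        positions = [s.position for s in self.ctcf_sites]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise LocusValidationError("CTCF site positions must be strictly increasing")
        vks = self.vk_segments
        for a, b in zip(vks, vks[1:]):
            if b.start < a.end:
                raise LocusValidationError(f"overlapping Vk segments {a.id} / {b.id}")
        for s in vks:
            t0, t1 = self.tad_of(s.start), self.tad_of(s.end - 1)
            if t0 is None or t0 != t1:
                raise LocusValidationError(f"Vk segment {s.id} not inside exactly one TAD")
            if not self.snps_in(s.start, s.end):
                raise LocusValidationError(f"Vk segment {s.id} has no SNP")
        jks = self.jk_segments
        if jks:
            lo, hi = min(s.start for s in jks), max(s.end for s in jks)
            if not self.snps_in(lo, hi):
                raise LocusValidationError("Jk cluster has no SNP")
        for snp in self.snps:
            if snp.quality < SNP_MIN_QUALITY:
                raise LocusValidationError(f"SNP at {snp.position} below quality {SNP_MIN_QUALITY}")
        b6 = self.reference_sequences.get("B6", "")
        cast = self.reference_sequences.get("CAST", "")
        if len(b6) != len(cast) or len(b6) != self.length:
            raise LocusValidationError("haplotype sequences must both match the locus length")
        snp_pos = set(self._snp_positions)
        for p in np.flatnonzero(np.frombuffer(b6.encode(), np.uint8) != np.frombuffer(cast.encode(), np.uint8)):
            if int(p) not in snp_pos:
                raise LocusValidationError(f"haplotypes differ at non-SNP position {p}")


def signed_distance_and_orientation(segment: Segment, site: CTCFSite,
                                    anchor: str = "tss") -> tuple[int, str]:
    """Signed segment-to-site distance and away/toward orientation.

    Distance is (segment anchor point - site position) on the reference, so
    segments 5' of the site get negative distances and those 3' positive.
    The anchor point is the transcription start site by default; ``start`` and
    ``midpoint`` are strand-independent alternatives (under which the distance
    is invariant to flipping the segment's orientation).  A segment is
    'away'-oriented when transcription points outward from the site: a plus
    segment 3' of the site or a minus segment 5' of it.  At distance zero the
    tie resolves to 'away' (transcription necessarily proceeds outward from
    the site itself).
    """
    if anchor == "tss":
        point = segment.tss
    elif anchor == "start":
        point = segment.start
    elif anchor == "midpoint":
        point = (segment.start + segment.end) // 2
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    distance = point - site.position
    if distance == 0:
        return 0, "away"
    if segment.orientation == "+":
        orient = "away" if distance > 0 else "toward"
    else:
        orient = "away" if distance < 0 else "toward"
    return distance, orient


# ---------------------------------------------------------------------------
# Default desk-scale locus
# ---------------------------------------------------------------------------

_CTCF_POSITIONS = {
    "S1": 2_000, "S2": 40_000, "S3": 80_000, "S4": 120_000,
    "S5": 150_000, "S6": 225_000, "S7": 260_000, "S8": 300_000,
}

_DISTAL_NAMES = [
    "Vk2-137", "Vk1-135", "Vk1-133", "Vk17-127", "Vk14-126", "Vk9-124",
    "Vk1-122", "Vk9-120", "Vk11-119", "Vk1-117", "Vk2-112", "Vk14-111",
    "Vk4-109", "Vk12-104", "Vk1-99", "Vk10-96", "Vk10-95", "Vk19-93",
    "Vk4-91", "Vk13-84",
]
_INTERMEDIATE_NAMES = [
    "Vk4-81", "Vk4-79", "Vk4-74", "Vk4-72", "Vk4-68", "Vk4-61",
    "Vk4-55", "Vk4-50", "Vk6-40", "Vk6-32",
]
_PROXIMAL_NAMES = [
    "Vk8-30", "Vk8-28", "Vk6-25", "Vk6-23", "Vk6-20", "Vk6-17",
    "Vk6-15", "Vk3-12", "Vk3-7", "Vk3-1",
]

# The nine most highly used Vk genes.
HIGHLY_USED_NAMES = frozenset({
    "Vk1-135", "Vk17-127", "Vk9-120", "Vk1-117", "Vk10-96",
    "Vk10-95", "Vk6-23", "Vk6-17", "Vk6-15",
})

# Deterministic mixed-orientation pattern over the 40 Vk segments.
_VK_STRANDS = "++-+-++--++-+--++-+-+-++--+++-+--++-+-+-"
# Non-functional Vk segments (pseudogenes / ORF-disrupted in the toy locus).
_NONFUNCTIONAL = frozenset({
    "Vk1-133", "Vk9-124", "Vk14-111", "Vk1-99", "Vk19-93", "Vk4-79",
    "Vk4-61", "Vk6-40", "Vk8-28", "Vk3-7",
})
# Vk promoters pre-loaded with E2A in pro-B cells.
_E2A_BOUND = frozenset({
    "Vk1-135", "Vk17-127", "Vk9-120", "Vk1-117", "Vk10-96", "Vk10-95",
    "Vk6-23", "Vk2-112", "Vk4-74", "Vk4-50", "Vk8-30", "Vk3-12",
})

VK_LENGTH = 300
_LOCUS_LENGTH = 340_000
_REFERENCE_SEED = 28_082_018  # fixture constant; default_locus is deterministic


def _build_vk(name: str, start: int, klass: str, strand: str) -> Segment:
    return Segment(
        id=name, start=start, end=start + VK_LENGTH, orientation=strand, klass=klass,
        functional=name not in _NONFUNCTIONAL,
        highly_used=name in HIGHLY_USED_NAMES,
        e2a_bound=name in _E2A_BOUND,
    )


def default_locus() -> LocusModel:
    """Build the packaged desk-scale Igkappa locus (deterministic)."""
    segments: list[Segment] = []
    strands = iter(_VK_STRANDS)
    for i, name in enumerate(_DISTAL_NAMES):
        segments.append(_build_vk(name, 5_000 + i * 7_200, "Vk_distal", next(strands)))
    for i, name in enumerate(_INTERMEDIATE_NAMES):
        segments.append(_build_vk(name, 152_000 + i * 7_000, "Vk_intermediate", next(strands)))
    for i, name in enumerate(_PROXIMAL_NAMES):
        segments.append(_build_vk(name, 227_000 + i * 7_000, "Vk_proximal", next(strands)))

    for i in range(4):
        start = 303_000 + i * 400
        segments.append(Segment(f"Jk{i + 1}", start, start + 50, "+", "Jk"))
    segments.append(Segment("Ck", 306_000, 306_800, "+", "Ck"))
    for i in range(3):
        start = 320_000 + i * 2_000
        segments.append(Segment(f"Igl{i + 1}", start, start + 300, "+", "Igl"))
    segments.append(Segment("Ctrl-act1", 328_000, 329_200, "+", "control_gene"))
    segments.append(Segment("Ctrl-act2", 330_000, 330_800, "-", "control_gene"))
    segments.append(Segment("Ctrl-rep1", 332_000, 333_200, "+", "control_gene"))
    segments.append(Segment("Ctrl-rep2", 334_000, 335_000, "-", "control_gene"))

    jk_promoters = {"Jkp1": (301_800, 301_900), "Jkp2": (302_600, 302_700)}

    snps: list[HaplotypeSNP] = []
    snp_positions: list[int] = []
    for s in segments:
        if s.is_vk:
            snp_positions += [s.start + 80, s.end - 20]
        elif s.klass == "Jk":
            snp_positions.append(s.start + 15)
    for _, (p_start, _) in sorted(jk_promoters.items()):
        snp_positions.append(p_start + 30)

    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.array(list("ACGT"))
    b6 = rng.choice(bases, size=_LOCUS_LENGTH)

    def plant(pos: int, motif: str) -> None:
        b6[pos:pos + len(motif)] = list(motif)

    for s in segments:
        plant(s.end, "GT")                       # sense splice donor
        plant(s.end + ANTISENSE_OFFSET, "CT")    # antisense donor (reference strand)
        if s.klass == "Jk":
            plant(s.start - 39, RSS_NONAMER)     # nonamer + 23-bp spacer + heptamer
            plant(s.start - 7, RSS_HEPTAMER)
        else:
            plant(s.start - 2, "AG")             # sense splice acceptor
            plant(s.start - ANTISENSE_OFFSET - 2, "AC")
        if s.is_vk:
            plant(s.end + 8, RSS_HEPTAMER)       # Vk RSS: heptamer + 12-bp spacer + nonamer
            plant(s.end + 27, RSS_NONAMER)

    cast = b6.copy()
    order = "ACGT"
    for pos in sorted(snp_positions):
        ref = str(b6[pos])
        alt = order[(order.index(ref) + 1) % 4]
        cast[pos] = alt
        snps.append(HaplotypeSNP(pos, ref, alt, quality=228.0))

    return LocusModel(
        chrom="Igk_toy",
        length=_LOCUS_LENGTH,
        segments=segments,
        ctcf_sites=[CTCFSite(k, v) for k, v in _CTCF_POSITIONS.items()],
        tads=_make_tads([CTCFSite(k, v) for k, v in _CTCF_POSITIONS.items()]),
        snps=snps,
        reference_sequences={"B6": "".join(b6), "CAST": "".join(cast)},
        jk_promoters=jk_promoters,
    )


def _make_tads(ctcf_sites: list[CTCFSite]) -> list[TAD]:
    by_id = {s.id: s for s in ctcf_sites}
    tads = []
    for name, left, right in TAD_ANCHORS:
        if left not in by_id or right not in by_id:
            raise LocusValidationError(f"TAD {name}: anchor {left}/{right} missing from CTCF table")
        tads.append(TAD(name, left, right, by_id[left].position, by_id[right].position))
    return tads


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "klass", "functional", "flags"]


def load_locus(segment_table: str, ctcf_table: str, snp_table: str, fasta: str) -> LocusModel:
    """Load and validate a locus from its four on-disk tables.

    ``segment_table`` is BED6+3 (chrom start end name score strand klass
    functional flags); rows with klass ``jk_promoter`` populate the J-kappa
    promoter map rather than the segment list.  ``ctcf_table`` is a TSV of
    (id, position).  ``snp_table`` is a minimal VCF; records below quality 100
    are dropped.  ``fasta`` holds the two haplotype records B6 and CAST.
    """
    bed = pd.read_csv(segment_table, sep="\t", names=_BED_COLUMNS, comment="#", dtype=str)
    if bed.empty:
        raise LocusValidationError("no segments")
    fa = Fasta(fasta)
    if "B6" not in fa or "CAST" not in fa:
        raise LocusValidationError("reference FASTA must contain records B6 and CAST")
    reference = {name: str(fa[name][:]).upper() for name in ("B6", "CAST")}
    length = len(reference["B6"])

    segments, jk_promoters = [], {}
    chrom = bed.iloc[0]["chrom"]
    for row in bed.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not (0 <= start < end <= length):
            raise LocusValidationError(f"{row.name}: coordinates outside reference length")
        if row.klass == "jk_promoter":
            jk_promoters[row.name] = (start, end)
            continue
        flags = set() if row.flags in (".", "", None) else set(str(row.flags).split(","))
        segments.append(Segment(
            id=row.name, start=start, end=end, orientation=row.strand, klass=row.klass,
            functional=str(row.functional).lower() in ("1", "true", "yes"),
            highly_used="highly_used" in flags, e2a_bound="e2a_bound" in flags,
        ))

    ctcf_df = pd.read_csv(ctcf_table, sep="\t")
    ctcf_sites = [CTCFSite(str(r["id"]), int(r["position"])) for _, r in ctcf_df.iterrows()]

    snps = []
    with pysam.VariantFile(snp_table) as vcf:
        for rec in vcf:
            if rec.qual is None or rec.qual < SNP_MIN_QUALITY:
                continue
            snps.append(HaplotypeSNP(rec.pos - 1, rec.ref, rec.alts[0], float(rec.qual)))

    return LocusModel(
        chrom=chrom, length=length, segments=segments, ctcf_sites=ctcf_sites,
        tads=_make_tads(ctcf_sites), snps=snps, reference_sequences=reference,
        jk_promoters=jk_promoters,
    )


def write_locus(model: LocusModel, out_dir: str) -> dict[str, str]:
    """Write the four locus tables; returns the file paths keyed by kind."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "segments": os.path.join(out_dir, "segments.bed"),
        "ctcf": os.path.join(out_dir, "ctcf.tsv"),
        "snps": os.path.join(out_dir, "snps.vcf"),
        "fasta": os.path.join(out_dir, "reference.fa"),
    }
    with open(paths["segments"], "w") as fh:
        for s in model.segments:
            flags = ",".join(f for f, on in (("highly_used", s.highly_used), ("e2a_bound", s.e2a_bound)) if on) or "."
            fh.write(f"{model.chrom}\t{s.start}\t{s.end}\t{s.id}\t0\t{s.orientation}\t"
                     f"{s.klass}\t{str(s.functional).lower()}\t{flags}\n")
        for name, (start, end) in sorted(model.jk_promoters.items()):
            fh.write(f"{model.chrom}\t{start}\t{end}\t{name}\t0\t+\tjk_promoter\ttrue\t.\n")
    with open(paths["ctcf"], "w") as fh:
        fh.write("id\tposition\n")
        for s in model.ctcf_sites:
            fh.write(f"{s.id}\t{s.position}\n")
    with open(paths["snps"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={model.chrom},length={model.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, snp in enumerate(model.snps):
            fh.write(f"{model.chrom}\t{snp.position + 1}\tsnp{i}\t{snp.b6_base}\t"
                     f"{snp.cast_base}\t{snp.quality:g}\tPASS\t.\n")
    with open(paths["fasta"], "w") as fh:
        for name in ("B6", "CAST"):
            fh.write(f">{name}\n")
            seq = model.reference_sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return paths


def locus_summary(model: LocusModel) -> dict:
    """Small JSON-able description used by the CLI validator."""
    return {
        "chrom": model.chrom,
        "length": model.length,
        "n_vk": len(model.vk_segments),
        "n_jk": len(model.jk_segments),
        "n_snps": len(model.snps),
        "tads": {t.name: [t.left_anchor, t.right_anchor] for t in model.tads},
        "highly_used": sorted(s.id for s in model.highly_used),
    }
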