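"""In-memory aligned-read container shared by the per-cell analyses.

:class:`Read` is a minimal SAM-record view (name, flag, 0-based start, MAPQ,
CIGAR, sequence) used internally for speed at cohort scale; pysam handles all
on-disk SAM I/O.  CIGAR is a tuple of (op, length) pairs with the usual SAM
operation characters.
"""

from __future__ import annotations

from bisect import bisect_left

import pysam

REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ2 = 0x80

_CIGAR_OPS = "MIDNSHP=X"


class Read:
    __slots__ = ("name", "flag", "start", "mapq", "cigar", "seq", "mate_start", "tlen")

    def __init__(self, name, start, cigar, seq, mapq=60, flag=0, mate_start=-1, tlen=0):
        self.name = name
        self.flag = flag
        self.start = start
        self.mapq = mapq
        self.cigar = cigar
        self.seq = seq
        self.mate_start = mate_start
        self.tlen = tlen

    @property
    def end(self) -> int:
        """Reference end (exclusive), spanning any N gaps."""
        return self.start + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Aligned reference blocks, splitting at N (skipped region) ops."""
        blocks, p, block_start = [], self.start, self.start
        for op, n in self.cigar:
            if op == "N":
                if p > block_start:
                    blocks.append((block_start, p))
                p += n
                block_start = p
            elif op in REF_CONSUMING:
                p += n
        if p > block_start:
            blocks.append((block_start, p))
        return blocks

    def junctions(self) -> list[tuple[int, int]]:
        """Genomic [start, end) intervals of the N gaps in this read."""
        out, p = [], self.start
        for op, n in self.cigar:
            if op == "N":
                out.append((p, p + n))
            if op in REF_CONSUMING:
                p += n
        return out

    def base_at(self, ref_pos: int) -> str | None:
        """The read base aligned to ``ref_pos``, or None if not aligned there."""
        p, q = self.start, 0
        for op, n in self.cigar:
            ref = op in REF_CONSUMING
            query = op in QUERY_CONSUMING
            if ref and query and p <= ref_pos < p + n:
                return self.seq[q + (ref_pos - p)]
            if ref:
                if p <= ref_pos < p + n:
                    return None  # deletion or skipped region
                p += n
            if query:
                q += n
        return None

    def cigarstring(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def _parse_cigar(cigarstring: str) -> tuple[tuple[str, int], ...]:
    out, n = [], 0
    for ch in cigarstring:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            out.append((ch, n))
            n = 0
    return tuple(out)


class MalformedCigarError(ValueError):
    pass


class CellAlignmentSet:
    """One cell's aligned reads against the locus, sorted by start."""

    def __init__(self, cell_id: str, chrom: str, reads: list[Read], ref_length: int = 0):
        self.cell_id = cell_id
        self.chrom = chrom
        self.reads = sorted(reads, key=lambda r: r.start)
        self.ref_length = ref_length
        self._starts = [r.start for r in self.reads]
        self._max_span = max((r.end - r.start for r in self.reads), default=0)

    def __len__(self) -> int:
        return len(self.reads)

    def fetch(self, start: int, end: int) -> list[Read]:
        """Reads overlapping [start, end)."""
        lo = bisect_left(self._starts, start - self._max_span)
        hi = bisect_left(self._starts, end)
        return [r for r in self.reads[lo:hi] if r.end > start]

    # -- SAM I/O (via pysam) ------------------------------------------------

    def to_sam(self, path: str) -> None:
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.chrom, "LN": self.ref_length or max((r.end for r in self.reads), default=1)}],
            "RG": [{"ID": self.cell_id}],
        })
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(header)
                a.query_name = r.name
                a.flag = r.flag
                a.reference_id = 0
                a.reference_start = r.start
                a.mapping_quality = r.mapq
                a.cigarstring = r.cigarstring()
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
                if r.is_paired:
                    a.next_reference_id = 0
                    a.next_reference_start = r.mate_start
                    a.template_length = r.tlen
                out.write(a)

    @classmethod
    def from_sam(cls, path: str, cell_id: str | None = None) -> "CellAlignmentSet":
        reads, chrom, ref_length, skipped = [], None, 0, 0
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            if fh.header.get("SQ"):
                chrom = fh.header["SQ"][0]["SN"]
                ref_length = fh.header["SQ"][0]["LN"]
            for a in fh:
                if a.is_unmapped and a.cigarstring is None:
                    continue
                try:
                    cigar = _parse_cigar(a.cigarstring)
                except Exception:
                    skipped += 1
                    continue
                reads.append(Read(
                    a.query_name, a.reference_start, cigar, a.query_sequence or "",
                    mapq=a.mapping_quality, flag=a.flag,
                    mate_start=a.next_reference_start, tlen=a.template_length,
                ))
        out = cls(cell_id or path, chrom or "", reads, ref_length)
        out.n_skipped = skipped
        return out
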