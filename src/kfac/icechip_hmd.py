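"""Spike-in calibrated ChIP quantitation (ICeChIP).

Histone modification density (HMD) expresses ChIP signal on an absolute
scale — the fraction of nucleosomes at a locus bearing the mark:

    HMD(p) = IP(p) / input(p) * 100% / target_barcode_enrichment

where the barcode enrichment of a semisynthetic nucleosome standard is its
IP / input read-count ratio, and the target standard's enrichment calibrates
the antibody's capture efficiency.  Antibody specificity is each standard's
enrichment as a fraction of the target's.

Fragment filtering follows the calibrated-ChIP pipeline: proper pairs only,
both mates MAPQ >= 20, pairs flattened to single fragment intervals, and
fragments longer than 220 bp (larger than a mononucleosome) removed.

Metagene profiles add 10%-of-gene-length cushions to both ends, split the
extended interval into exactly 100 bins oriented 5'->3', and average the
track per bin with exact base-pair overlap weighting; the TSS window is the
-10%..+10% region around the transcription start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAPQ_MIN = 20
FRAGMENT_MAX_LENGTH = 220


@dataclass
class BarcodeTable:
    """IP and input read counts per spike-in standard."""

    ip: dict[str, float]
    input: dict[str, float]
    target: str

    def validate(self) -> None:
        if self.target not in self.input or self.input[self.target] <= 0:
            raise ValueError("target standard needs a positive input count")


@dataclass
class HMDTrack:
    """Per-position HMD (percent); NaN where input coverage is zero."""

    hmd: np.ndarray
    ip_coverage: np.ndarray
    input_coverage: np.ndarray
    target_enrichment: float

    @property
    def defined(self) -> np.ndarray:
        return self.input_coverage > 0


@dataclass
class MetageneProfile:
    bins: np.ndarray  # 100 per-bin mean values, 5'->3'
    n_genes: int
    excluded: list = field(default_factory=list)


def filter_fragments(reads) -> list[tuple[int, int]]:
    """Flatten qualifying read pairs into fragment intervals.

    Keeps proper pairs whose mates are both mapped with MAPQ >= 20; each pair
    becomes one [start, end) fragment; fragments longer than 220 bp are
    dropped.  Unpaired or improperly paired reads are discarded.
    """
    pairs: dict[str, list] = {}
    for r in reads:
        if not r.is_paired or r.is_unmapped or r.mate_unmapped or not r.is_proper_pair:
            continue
        pairs.setdefault(r.name, []).append(r)
    fragments = []
    for name, mates in sorted(pairs.items()):
        if len(mates) != 2:
            continue
        if min(m.mapq for m in mates) < MAPQ_MIN:
            continue
        start = min(m.start for m in mates)
        end = max(m.end for m in mates)
        if end - start <= FRAGMENT_MAX_LENGTH:
            fragments.append((start, end))
    return sorted(fragments)


def fragments_to_coverage(fragments: list[tuple[int, int]], length: int) -> np.ndarray:
    cov = np.zeros(length + 1)
    for s, e in fragments:
        cov[s] += 1
        cov[min(e, length)] -= 1
    return np.cumsum(cov)[:length]


def barcode_enrichment(table: BarcodeTable) -> tuple[dict[str, float | None], float]:
    """Per-standard IP/input barcode-count ratio and the target's enrichment.

    Standards with zero input count get ``None`` (undefined, flagged).
    """
    table.validate()
    enrichment: dict[str, float | None] = {}
    for std in table.input:
        n_in = table.input[std]
        enrichment[std] = (table.ip.get(std, 0.0) / n_in) if n_in > 0 else None
    return enrichment, enrichment[table.target]


def specificity(enrichments: dict[str, float | None], target: str,
                mode: str = "target") -> dict[str, float]:
    """Each standard's capture as a fraction of the target's (default), or of
    the summed enrichment (``mode='sum'``)."""
    if enrichments.get(target) in (None, 0):
        raise ValueError("target enrichment must be positive")
    defined = {s: e for s, e in enrichments.items() if e is not None}
    denom = defined[target] if mode == "target" else sum(defined.values())
    return {s: e / denom for s, e in defined.items()}


def hmd_track(ip_coverage: np.ndarray, input_coverage: np.ndarray,
              target_enrichment: float) -> HMDTrack:
    """HMD(p) = IP(p)/input(p) * 100% / target enrichment; NaN where input is 0.

    Values are reported unclipped; sampling noise can push HMD above 100%.
    """
    if target_enrichment <= 0:
        raise ValueError("target enrichment must be positive")
    ip = np.asarray(ip_coverage, dtype=float)
    inp = np.asarray(input_coverage, dtype=float)
    hmd = np.full(ip.shape, np.nan)
    ok = inp > 0
    hmd[ok] = ip[ok] / inp[ok] * 100.0 / target_enrichment
    return HMDTrack(hmd=hmd, ip_coverage=ip, input_coverage=inp,
                    target_enrichment=target_enrichment)


def region_hmd(track: HMDTrack, start: int, end: int) -> float:
    """Window-averaged HMD over [start, end): ratio of mean coverages.

    Averaging IP and input before taking the ratio avoids the upward bias of
    averaging per-bp ratios (the input count in each denominator is noisy).
    """
    ip = track.ip_coverage[start:end].mean()
    inp = track.input_coverage[start:end].mean()
    if inp <= 0:
        return float("nan")
    return float(ip / inp * 100.0 / track.target_enrichment)


# ---------------------------------------------------------------------------
# metagene binning
# ---------------------------------------------------------------------------

def _interval_mean(values: np.ndarray, weights: np.ndarray,
                   cum_v: np.ndarray, cum_w: np.ndarray, a: float, b: float) -> float:
    """Weighted mean of a per-bp step function over the real interval [a, b)."""
    ia, ib = int(np.floor(a)), int(np.floor(b))
    if ia == ib:
        return values[ia] if weights[ia] > 0 else np.nan
    v = cum_v[ib] - cum_v[ia + 1] + values[ia] * weights[ia] * (ia + 1 - a)
    w = cum_w[ib] - cum_w[ia + 1] + weights[ia] * (ia + 1 - a)
    if b > ib and ib < len(values):
        v += values[ib] * weights[ib] * (b - ib)
        w += weights[ib] * (b - ib)
    return v / w if w > 0 else np.nan


def _gene_profile(values, weights, cum_v, cum_w, start, end, strand,
                  n_bins, cushion) -> np.ndarray:
    length = end - start
    pad = cushion * length
    edges = np.linspace(start - pad, end + pad, n_bins + 1)
    prof = np.array([_interval_mean(values, weights, cum_v, cum_w, edges[i], edges[i + 1])
                     for i in range(n_bins)])
    return prof[::-1] if strand == "-" else prof


def _as_intervals(genes):
    out = []
    for g in genes:
        if hasattr(g, "start"):
            out.append((g.start, g.end, getattr(g, "orientation", "+"), getattr(g, "id", "")))
        else:
            start, end = g[0], g[1]
            strand = g[2] if len(g) > 2 else "+"
            name = g[3] if len(g) > 3 else str(g)
            out.append((start, end, strand, name))
    return out


def _prepare(track) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    values = np.asarray(track.hmd if isinstance(track, HMDTrack) else track, dtype=float)
    weights = (~np.isnan(values)).astype(float)
    filled = np.nan_to_num(values)
    cum_v = np.concatenate([[0.0], np.cumsum(filled * weights)])
    cum_w = np.concatenate([[0.0], np.cumsum(weights)])
    return filled, weights, cum_v, cum_w


def metagene(track, genes, n_bins: int = 100, cushion: float = 0.10) -> MetageneProfile:
    """Average 100-bin profile over a gene set, with 10% cushions per side.

    ``track`` is an :class:`HMDTrack` or a per-bp array (NaN = undefined).
    Genes wholly or partly outside the track are excluded and reported.
    Minus-strand genes are reversed before averaging, so bin 0 is always the
    5' cushion end.
    """
    values, weights, cum_v, cum_w = _prepare(track)
    profiles, excluded = [], []
    for start, end, strand, name in _as_intervals(genes):
        length = end - start
        if length <= 0:
            excluded.append(name)
            continue
        pad = cushion * length
        if start - pad < 0 or end + pad > len(values):
            excluded.append(name)
            continue
        profiles.append(_gene_profile(values, weights, cum_v, cum_w,
                                      start, end, strand, n_bins, cushion))
    if not profiles:
        raise ValueError("no genes inside the track")
    with np.errstate(invalid="ignore"):
        bins = np.nanmean(np.vstack(profiles), axis=0)
    return MetageneProfile(bins=bins, n_genes=len(profiles), excluded=excluded)


def tss_window(track, genes, window: float = 0.10) -> float:
    """Mean track value over the -10%..+10% (of gene length) TSS window,
    strand-aware, averaged across genes."""
    values, weights, cum_v, cum_w = _prepare(track)
    means = []
    for start, end, strand, name in _as_intervals(genes):
        length = end - start
        tss = start if strand == "+" else end
        a, b = tss - window * length, tss + window * length
        if a < 0 or b > len(values):
            continue
        means.append(_interval_mean(values, weights, cum_v, cum_w, a, b))
    if not means:
        raise ValueError("no genes inside the track")
    return float(np.nanmean(means))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_bedgraph(values: np.ndarray, chrom: str, path: str) -> None:
    """Run-length-encoded bedgraph; NaN positions are omitted."""
    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[start] and not (
                    np.isnan(vals[i]) and np.isnan(vals[start])):
                if not np.isnan(vals[start]):
                    fh.write(f"{chrom}\t{start}\t{i}\t{vals[start]:g}\n")
                start = i


def read_bedgraph(path: str, length: int) -> np.ndarray:
    values = np.full(length, np.nan)
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        values[row.start:row.end] = row.value
    return values


def write_barcode_table(table: BarcodeTable, path: str) -> None:
    pd.DataFrame({
        "standard": list(table.input),
        "n_ip": [table.ip.get(s, 0) for s in table.input],
        "n_input": [table.input[s] for s in table.input],
    }).to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str, target: str) -> BarcodeTable:
    df = pd.read_csv(path, sep="\t")
    return BarcodeTable(ip=dict(zip(df["standard"], df["n_ip"])),
                        input=dict(zip(df["standard"], df["n_input"])), target=target)
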