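"""Ground-truth synthetic data: per-cell aligned reads and ICeChIP sequencing.

The cell generator emulates sorted F1 (B6 x CAST) small pre-B cells at the
four states the expression analysis distinguishes:

* ``no_expression`` — no V-kappa/J-kappa reads (a control gene is covered so
  the library is non-empty);
* ``poised`` — biallelic germline J-kappa transcription from both promoters
  (with intact RSS context in the reads), plus one to three monoallelic
  read-through transcription units confined to single TADs, emitted as
  SNP-bearing coverage reads and spliced reads whose CIGAR N gaps join
  transcribed segments over canonical GT..AG junctions;
* ``recomb_one_allele`` — split reads fusing a V-kappa coding end to a
  J-kappa 5' end on one allele;
* ``recomb_two_or_lambda`` — junctions on both alleles, or junctions on one
  allele plus Ig-lambda expression.

Transcription units anchor either at a TAD-boundary CTCF site or at a V-kappa
promoter (E2A-loaded promoters and away-oriented genes favoured by the
configured odds); the run length along the chromatin is geometric with mean
``mean_run_length`` and is truncated at the TAD boundary, so no planted unit
ever crosses a TAD anchor.  Within a cell, units occupy distinct TADs and all
segments of a unit are transcribed from the unit's single allele.  With
probability ``p_same_allele_locuswide`` every unit in a cell uses the same
allele; otherwise at least two units are planted on opposite alleles.

Sequencing error is i.i.d. base substitution (no indels).  All randomness
flows from one seed; reruns are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from kfac.alignments import CellAlignmentSet, Read, FLAG_REVERSE
from kfac.locus_model import ANTISENSE_OFFSET, LocusModel, Segment

ALLELES = ("B6", "CAST")
STATES = ("no_expression", "poised", "recomb_one_allele", "recomb_two_or_lambda")

# Cohort composition mirroring the categorized single-cell libraries of the
# study (51 silent / 72 poised / 81 one-allele / 51 two-allele-or-lambda).
_DEFAULT_STATE_PROBS = {
    "no_expression": 51 / 255,
    "poised": 72 / 255,
    "recomb_one_allele": 81 / 255,
    "recomb_two_or_lambda": 51 / 255,
}

ICECHIP_STANDARDS = ("H3K27me3", "H3K4me3", "H3K9me3", "H3K36me3", "H3K79me2")


@dataclass
class SimParams:
    """Knobs of the cell generator; defaults are the emulated study conditions."""

    n_cells: int = 268
    state_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_PROBS))
    p_same_allele_locuswide: float = 0.72
    anchor_mix: float = 0.5            # P(unit anchors at a CTCF site vs a promoter)
    orientation_bias_odds: float = 3.0  # promoter-anchor odds favouring away-oriented Vk
    e2a_odds: float = 4.0               # promoter-anchor odds favouring E2A-bound promoters
    mean_run_length: float = 40_000.0   # bp; geometric, truncated at the TAD boundary
    antisense_fraction: float = 0.1
    read_length: int = 75
    depth: float = 40.0                # per-base coverage over each expressed segment
    jk_depth: float = 20.0             # per-allele coverage over the germline Jk window
    junction_read_count: int = 12      # reads supporting each planted splice junction
    base_error_rate: float = 0.001
    cross_tad_junctions_per_cell: int = 0  # deliberate anomalies, for boundary testing
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.state_probabilities.values())
        if not np.isclose(total, 1.0):
            raise ValueError("state probabilities must sum to 1")
        if any(p < 0 for p in self.state_probabilities.values()):
            raise ValueError("state probabilities must be non-negative")
        if set(self.state_probabilities) - set(STATES):
            raise ValueError(f"unknown states {set(self.state_probabilities) - set(STATES)}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0 <= self.p_same_allele_locuswide <= 1:
            raise ValueError("p_same_allele_locuswide must be in [0, 1]")
        if self.state_probabilities.get("poised", 0) > 0 and self.depth <= 0:
            raise ValueError("poised cells requested but depth is zero")


@dataclass
class UnitTruth:
    """One planted transcription unit."""

    anchor: str               # CTCF site id or anchor segment id
    allele: str
    tad: str
    strand: str               # transcript direction on the reference
    segment_ids: list[str]    # genomic order
    span: int                 # bp, 5'-most to 3'-most segment boundary


@dataclass
class CellTruth:
    cell_id: str
    state: str
    chosen_allele_per_tad: dict[str, str] = field(default_factory=dict)
    transcription_units: list[UnitTruth] = field(default_factory=list)
    jk_germline: str = "none"  # biallelic / monoallelic / none
    planted_junctions: list[tuple[str, str, int]] = field(default_factory=list)
    recombination: list[tuple[str, str, str]] = field(default_factory=list)  # (V, J, allele)
    cross_tad_junctions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def same_allele_locuswide(self) -> bool:
        return len(set(self.chosen_allele_per_tad.values())) <= 1


# ---------------------------------------------------------------------------
# read emission helpers
# ---------------------------------------------------------------------------

class _CellEmitter:
    def __init__(self, model: LocusModel, params: SimParams, cell_id: str, rng):
        self.model = model
        self.params = params
        self.cell_id = cell_id
        self.rng = rng
        self.reads: list[Read] = []
        self._n = 0

    def _add(self, start, cigar, seq, flag=0):
        self._n += 1
        self.reads.append(Read(f"{self.cell_id}:r{self._n}", start, cigar, seq, mapq=60, flag=flag))

    def tile(self, start: int, end: int, allele: str, coverage: float) -> None:
        """Evenly tiled plain-M reads giving ~``coverage`` over [start, end)."""
        rl = self.params.read_length
        hap = self.model.reference_sequences[allele]
        lo = max(0, start - rl + 1)
        hi = min(len(hap) - rl, end - 1)
        n = max(1, int(np.ceil(coverage * (hi - lo + rl) / rl)))
        cigar = (("M", rl),)
        for p in np.unique(np.linspace(lo, hi, n).round().astype(int)):
            self._add(int(p), cigar, hap[p:p + rl])

    def junction_reads(self, left_edge: int, right_edge: int, allele: str,
                       count: int, antisense: bool) -> None:
        """``count`` split reads whose N gap spans [left_edge, right_edge)."""
        rl = self.params.read_length
        hap = self.model.reference_sequences[allele]
        gap = right_edge - left_edge
        flag = FLAG_REVERSE if antisense else 0
        for i in range(count):
            left_len = 25 + (i * 7) % 30
            right_len = rl - left_len
            start = left_edge - left_len
            seq = hap[start:left_edge] + hap[right_edge:right_edge + right_len]
            self._add(start, (("M", left_len), ("N", gap), ("M", right_len)), seq, flag=flag)

    def vj_junction_reads(self, v: Segment, j: Segment, allele: str, count: int) -> None:
        """Recombination-product split reads fusing the Vk coding end to the Jk 5' end."""
        rl = self.params.read_length
        hap = self.model.reference_sequences[allele]
        gap = j.start - v.end
        for i in range(count):
            left_len = 30 + (i * 5) % 25   # always covers the Vk coding-end SNP (end-20)
            right_len = rl - left_len      # always covers the Jk SNP (start+15)
            start = v.end - left_len
            seq = hap[start:v.end] + hap[j.start:j.start + right_len]
            self._add(start, (("M", left_len), ("N", gap), ("M", right_len)), seq)

    def inject_errors(self) -> None:
        rate = self.params.base_error_rate
        if rate <= 0 or not self.reads:
            return
        total = sum(len(r.seq) for r in self.reads)
        k = self.rng.binomial(total, rate)
        if k == 0:
            return
        idx = self.rng.integers(0, len(self.reads), size=k)
        for i in idx:
            r = self.reads[i]
            pos = int(self.rng.integers(0, len(r.seq)))
            old = r.seq[pos]
            new = "ACGT"[int(self.rng.integers(0, 4))]
            while new == old:
                new = "ACGT"[int(self.rng.integers(0, 4))]
            r.seq = r.seq[:pos] + new + r.seq[pos + 1:]


# ---------------------------------------------------------------------------
# transcription-unit planting
# ---------------------------------------------------------------------------

def _promoter_anchor_weights(model: LocusModel, segments: list[Segment], params: SimParams):
    w = np.ones(len(segments))
    for i, s in enumerate(segments):
        if s.e2a_bound:
            w[i] *= params.e2a_odds
        if model.orientation_class(s) == "away":
            w[i] *= params.orientation_bias_odds
    return w / w.sum()


def _plant_unit(model: LocusModel, params: SimParams, tad_name: str, allele: str, rng) -> UnitTruth:
    tad = model.tad(tad_name)
    tad_vks = [s for s in model.vk_segments if s.start >= tad.start and s.end <= tad.end]
    length = int(rng.geometric(1.0 / params.mean_run_length))

    if rng.random() < params.anchor_mix:
        # anchor at a TAD-boundary CTCF site, transcribing into the TAD
        site_id = tad.left_anchor if rng.random() < 0.5 else tad.right_anchor
        site = model.ctcf(site_id)
        anchor = site_id
        if site_id == tad.left_anchor:
            strand, a0 = "+", site.position
        else:
            strand, a1 = "-", site.position
    else:
        seg = tad_vks[int(rng.choice(len(tad_vks), p=_promoter_anchor_weights(model, tad_vks, params)))]
        anchor = seg.id
        strand = seg.orientation
        if rng.random() < params.antisense_fraction:
            strand = "-" if strand == "+" else "+"
        length = max(length, seg.end - seg.start)  # the anchor gene itself is transcribed
        a0, a1 = seg.start, seg.end

    if strand == "+":
        run = (a0, min(a0 + length, tad.end))
    else:
        run = (max(a1 - length, tad.start), a1)
    covered = [s for s in tad_vks if s.start >= run[0] and s.end <= run[1]]
    if not covered:
        # extend the run to the nearest segment in the transcription direction
        if strand == "+":
            nxt = min((s for s in tad_vks if s.start >= run[0]), key=lambda s: s.start, default=None)
            if nxt is None:
                strand, a1 = "-", a0
                nxt = max((s for s in tad_vks if s.end <= a1), key=lambda s: s.end)
                covered = [nxt]
            else:
                covered = [nxt]
        else:
            prv = max((s for s in tad_vks if s.end <= run[1]), key=lambda s: s.end, default=None)
            if prv is None:
                strand, a0 = "+", run[1]
                prv = min((s for s in tad_vks if s.start >= a0), key=lambda s: s.start)
            covered = [prv]
    covered.sort(key=lambda s: s.start)
    span = covered[-1].end - covered[0].start
    return UnitTruth(anchor=anchor, allele=allele, tad=tad_name, strand=strand,
                     segment_ids=[s.id for s in covered], span=span)


def _emit_unit(emitter: _CellEmitter, unit: UnitTruth, truth: CellTruth) -> None:
    model, params = emitter.model, emitter.params
    segs = [model.segment(i) for i in unit.segment_ids]
    for s in segs:
        emitter.tile(s.start, s.end, unit.allele, params.depth)
    antisense = unit.strand == "-"
    off = ANTISENSE_OFFSET if antisense else 0
    for a, b in zip(segs, segs[1:]):  # genomic order
        emitter.junction_reads(a.end + off, b.start - off, unit.allele,
                               params.junction_read_count, antisense)
        donor, acceptor = (b.id, a.id) if antisense else (a.id, b.id)
        truth.planted_junctions.append((donor, acceptor, params.junction_read_count))


def _emit_germline_jk(emitter: _CellEmitter, alleles: tuple[str, ...]) -> None:
    model, params = emitter.model, emitter.params
    jks = model.jk_segments
    window = (jks[0].start - 250, jks[-1].end + 50)
    for allele in alleles:
        emitter.tile(window[0], window[1], allele, params.jk_depth)
        for start, end in model.jk_promoters.values():
            emitter.tile(start - 20, end + 20, allele, 5.0)


def _pick_tads_and_alleles(params: SimParams, rng) -> dict[str, str]:
    tad_names = ("distal", "intermediate", "proximal")
    if rng.random() < params.p_same_allele_locuswide:
        n_units = int(rng.integers(1, 4))
        tads = rng.choice(3, size=n_units, replace=False)
        allele = ALLELES[int(rng.integers(0, 2))]
        return {tad_names[t]: allele for t in tads}
    n_units = int(rng.integers(2, 4))
    tads = sorted(rng.choice(3, size=n_units, replace=False))
    alleles = [ALLELES[int(rng.integers(0, 2))] for _ in tads]
    if len(set(alleles)) == 1:  # force a genuinely non-locuswide cell
        alleles[int(rng.integers(0, len(alleles)))] = (
            "CAST" if alleles[0] == "B6" else "B6")
    return {tad_names[t]: a for t, a in zip(tads, alleles)}


def _simulate_one_cell(model: LocusModel, params: SimParams, cell_id: str,
                       state: str, rng) -> tuple[CellTruth, CellAlignmentSet]:
    truth = CellTruth(cell_id=cell_id, state=state)
    em = _CellEmitter(model, params, cell_id, rng)

    if state == "no_expression":
        controls = [s for s in model.segments if s.klass == "control_gene"]
        ctrl = controls[int(rng.integers(0, len(controls)))]
        em.tile(ctrl.start, ctrl.end, "B6", 8.0)

    elif state == "poised":
        truth.jk_germline = "biallelic"
        _emit_germline_jk(em, ALLELES)
        truth.chosen_allele_per_tad = _pick_tads_and_alleles(params, rng)
        for tad_name, allele in truth.chosen_allele_per_tad.items():
            unit = _plant_unit(model, params, tad_name, allele, rng)
            truth.transcription_units.append(unit)
            _emit_unit(em, unit, truth)
        for _ in range(params.cross_tad_junctions_per_cell):
            tads = rng.choice(3, size=2, replace=False)
            names = ("distal", "intermediate", "proximal")
            pick = []
            for t in tads:
                tad = model.tad(names[t])
                vks = [s for s in model.vk_segments if s.start >= tad.start and s.end <= tad.end]
                pick.append(vks[int(rng.integers(0, len(vks)))])
            a, b = sorted(pick, key=lambda s: s.start)
            allele = next(iter(truth.chosen_allele_per_tad.values()))
            em.junction_reads(a.end, b.start, allele, params.junction_read_count, False)
            truth.cross_tad_junctions.append((a.id, b.id))

    elif state == "recomb_one_allele":
        allele = ALLELES[int(rng.integers(0, 2))]
        v, j = _pick_vj(model, rng)
        em.vj_junction_reads(v, j, allele, params.junction_read_count)
        truth.recombination.append((v.id, j.id, allele))

    elif state == "recomb_two_or_lambda":
        if rng.random() < 0.5:
            for allele in ALLELES:
                v, j = _pick_vj(model, rng)
                em.vj_junction_reads(v, j, allele, params.junction_read_count)
                truth.recombination.append((v.id, j.id, allele))
        else:
            allele = ALLELES[int(rng.integers(0, 2))]
            v, j = _pick_vj(model, rng)
            em.vj_junction_reads(v, j, allele, params.junction_read_count)
            truth.recombination.append((v.id, j.id, allele))
            igls = [s for s in model.segments if s.klass == "Igl"]
            igl = igls[int(rng.integers(0, len(igls)))]
            em.tile(igl.start, igl.end, allele, 15.0)
    else:
        raise ValueError(f"unknown state {state}")

    em.inject_errors()
    return truth, CellAlignmentSet(cell_id, model.chrom, em.reads, model.length)


def _pick_vj(model: LocusModel, rng) -> tuple[Segment, Segment]:
    functional = [s for s in model.vk_segments if s.functional]
    jks = model.jk_segments
    return (functional[int(rng.integers(0, len(functional)))],
            jks[int(rng.integers(0, len(jks)))])


def simulate_cells(model: LocusModel, params: SimParams,
                   out_dir: str | None = None) -> list[tuple[CellTruth, CellAlignmentSet]]:
    """Simulate a cohort; optionally write one SAM per cell plus a truth sidecar.

    Deterministic given ``params.seed``: reruns produce byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    state_names = list(params.state_probabilities)
    probs = np.array([params.state_probabilities[s] for s in state_names])
    states = rng.choice(len(state_names), size=params.n_cells, p=probs)
    out = []
    for i in range(params.n_cells):
        cell_id = f"cell{i:04d}"
        out.append(_simulate_one_cell(model, params, cell_id, state_names[states[i]], rng))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        sidecar = {}
        for truth, aln in out:
            aln.to_sam(os.path.join(out_dir, f"{truth.cell_id}.sam"))
            sidecar[truth.cell_id] = asdict(truth)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return out


def simulate_expression_events(model: LocusModel, n_cells: int,
                               orientation_bias_odds: float = 1.0,
                               e2a_odds: float = 1.0,
                               mean_events_per_cell: float = 3.0,
                               rng=None, seed: int | None = None) -> list[tuple[str, str]]:
    """Draw per-cell V-kappa expression events for the bias statistics.

    Each cell expresses a small random set of distinct V-kappa genes, drawn
    without replacement with weights ``e2a_odds`` for E2A-bound promoters and
    ``orientation_bias_odds`` for away-oriented genes (both 1 = uniform null).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vks = model.vk_segments
    w = np.ones(len(vks))
    for i, s in enumerate(vks):
        if s.e2a_bound:
            w[i] *= e2a_odds
        if model.orientation_class(s) == "away":
            w[i] *= orientation_bias_odds
    w = w / w.sum()
    events = []
    n_events = np.maximum(1, rng.poisson(mean_events_per_cell, size=n_cells))
    for c in range(n_cells):
        k = min(int(n_events[c]), len(vks))
        for idx in rng.choice(len(vks), size=k, replace=False, p=w):
            events.append((f"cell{c:04d}", vks[idx].id))
    return events


# ---------------------------------------------------------------------------
# ICeChIP simulation
# ---------------------------------------------------------------------------

@dataclass
class ChipTruth:
    """Planted chromatin state and spike-in standard behaviour."""

    planted_hmd: np.ndarray                 # per-position modification fraction in [0, 1]
    standard_capture: dict[str, float]      # antibody capture efficiency per standard
    barcode_counts_input: dict[str, int]
    target_standard: str = "H3K27me3"

    def validate(self) -> None:
        if np.any(self.planted_hmd < 0) or np.any(self.planted_hmd > 1):
            raise ValueError("planted HMD must lie in [0, 1]")
        if any(c < 0 for c in self.barcode_counts_input.values()):
            raise ValueError("barcode counts must be non-negative")
        if self.target_standard not in self.standard_capture:
            raise ValueError("target standard missing from capture map")


@dataclass
class IceChipData:
    ip_coverage: np.ndarray
    input_coverage: np.ndarray
    ip_barcodes: dict[str, float]
    input_barcodes: dict[str, float]


def default_chip_truth(model: LocusModel, target: str = "H3K27me3") -> ChipTruth:
    """Chromatin emulating the study: high HMD at repressed control genes, low
    at activated controls, and V-kappa comparable to active genes."""
    hmd = np.full(model.length, 0.15)
    for s in model.segments:
        if s.is_vk:
            hmd[s.start:s.end] = 0.08
        elif s.id.startswith("Ctrl-act"):
            hmd[s.start:s.end] = 0.05
        elif s.id.startswith("Ctrl-rep"):
            hmd[s.start:s.end] = 0.90
    capture = {s: (1.0 if s == target else 0.05) for s in ICECHIP_STANDARDS}
    counts = {s: 100_000 for s in ICECHIP_STANDARDS}
    return ChipTruth(planted_hmd=hmd, standard_capture=capture,
                     barcode_counts_input=counts, target_standard=target)


def simulate_icechip(model: LocusModel, truth: ChipTruth, depth: float, seed: int = 0,
                     noise: str = "poisson") -> IceChipData:
    """Paired IP/input coverage plus spike-in barcode counts.

    Input coverage is uniform at ``depth``; IP coverage at position p has
    expectation ``depth * planted_hmd(p) * capture(target)``; IP barcode
    counts have expectation proportional to each standard's capture
    efficiency.  ``noise='poisson'`` samples counts; ``noise='none'`` returns
    the expectations exactly (closed-form recovery checks).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    truth.validate()
    capture_t = truth.standard_capture[truth.target_standard]
    ip_mean = depth * truth.planted_hmd * capture_t
    if noise == "none":
        ip = ip_mean.astype(float)
        inp = np.full(model.length, float(depth))
        ip_bc = {s: truth.barcode_counts_input[s] * truth.standard_capture[s]
                 for s in truth.standard_capture}
        in_bc = {s: float(truth.barcode_counts_input[s]) for s in truth.standard_capture}
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        ip = rng.poisson(ip_mean).astype(float)
        inp = rng.poisson(depth, size=model.length).astype(float)
        ip_bc = {s: float(rng.poisson(truth.barcode_counts_input[s] * truth.standard_capture[s]))
                 for s in truth.standard_capture}
        in_bc = {s: float(rng.poisson(truth.barcode_counts_input[s]))
                 for s in truth.standard_capture}
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    return IceChipData(ip_coverage=ip, input_coverage=inp,
                       ip_barcodes=ip_bc, input_barcodes=in_bc)
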