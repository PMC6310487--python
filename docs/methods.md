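# Methods

## The coordinate frame

All analyses run against a `LocusModel`: gene segments with 0-based half-open
intervals (BED convention), eight CTCF sites S1 < … < S8, the three Vκ TADs
they anchor (distal = S1–S5, intermediate = S5–S6, proximal = S6–S8), a
B6-vs-CAST SNP table (records below quality 100 are dropped at load time), and
the two haplotype reference sequences, which differ only at SNP positions.

TAD membership is half-open: a position belongs to the TAD whose interval is
`[left anchor, right anchor)`, so a shared anchor (S5, S6) belongs to the TAD
on its right. This makes boundary queries deterministic; the choice is a
convention, not a biological claim.

Distances from CTCF sites anchor at the segment's transcription start site by
default (`anchor="tss"`); `start` and `midpoint` are available since figure
conventions for "gene position" vary. A segment is *away*-oriented when
transcription points outward from the site (plus strand 3′ of the site, minus
strand 5′ of it); at distance zero the tie resolves to *away*, since
transcription from the site itself necessarily proceeds outward. Nearest-site
ties resolve to the 5′ site.

### The packaged toy locus

`default_locus()` builds a deterministic desk-scale Igκ: 40 Vκ segments
(300 bp each) over ~300 kb in the three TADs (20 distal, 10 intermediate, 10
proximal), mixed orientations, the nine most highly used Vκ gene names
flagged, 12 E2A-preloaded promoters, 4 Jκ segments with two upstream germline
promoters, Cκ, 3 Igλ segments and 4 control genes, on a 340 kb reference.
Structural guarantees the tests rely on: every Vκ and Jκ segment contains at
least one SNP (so allelic assignment is always possible), canonical splice
dinucleotides are planted at segment edges (GT/AG at the sense edges; CT/AC
inset 4 bp for antisense junctions, so sense and antisense splice points never
collide), heptamer–23 bp spacer–nonamer RSS motifs sit 5′ of each Jκ, and a
heptamer–12 bp–nonamer sits 3′ of each Vκ. The Vκ RSS is placed on the
genomic 3′ side regardless of segment strand, and recombination junctions
always fuse `Vκ.end → Jκ.start` — a deletional-joining simplification that
keeps the junction geometry uniform.

## The synthetic cohort

The generator emulates sorted F1 small pre-B cells in four states; the default
state mix (19% silent, 28% poised, 32% one-allele-recombined, 20%
two-allele-or-λ) mirrors the composition of a categorized single-cell cohort
of this cell type. Defaults were fixed once, before any recovery testing, and
are treated as the study conditions.

**Poised cells.** Germline Jκ transcription is emitted biallelically: tiled
75-bp reads over the Jκ cluster and both promoters from both haplotypes
(per-allele coverage 20), which also supplies the RSS-bearing flank reads.
One to three read-through transcription units are planted, each in its own
TAD. A unit anchors either at a TAD-boundary CTCF site (transcribing into the
TAD) or at a Vκ promoter, with anchor probabilities 50/50; promoter choice is
weighted by odds 4 for E2A-preloaded promoters and 3 for away-from-CTCF
orientation, and 10% of promoter-anchored units run antisense. Run length
along the chromatin is geometric with mean 40 kb — memoryless, one knob — and
is truncated at the TAD boundary, so *no planted unit ever crosses a TAD
anchor*. 40 kb is the same ~13% of total locus span that the long
read-through transcripts reported for the full-scale locus represent. All
segments fully inside the run are transcribed from the unit's single allele:
tiled coverage reads (default per-base depth 40, enough that every SNP clears
the coverage-30 assignment threshold) plus 12 split reads per consecutive
segment pair whose `N` gap spans the planted junction.

With probability `p_same_allele_locuswide` (default 0.72) every unit in a
cell uses one allele; otherwise the cell is forced to carry at least two
units on *different* alleles, so the parameter is exactly the probability of
a locus-wide monoallelic cell and parameter-recovery tests have an unambiguous
target.

**Recombined cells** carry split reads fusing a functional Vκ coding end
(covering its coding-end SNP) to a Jκ 5′ end on one allele, or on both
alleles / one allele plus Igλ coverage for the two-or-λ state. **Silent
cells** cover only a control gene.

Sequencing error is i.i.d. base substitution (default 0.1%), no indels: it
stresses SNP calling without re-modelling alignment. Reads are emitted as
single-end records; pairing matters only for the ICeChIP fragment filter,
whose inputs are separate. Tiling positions are deterministic; given a seed,
reruns are byte-identical.

For the bias statistics, whose input is the list of (cell, expressed segment)
events rather than reads, a companion event-level generator draws each cell's
expressed Vκ set without replacement with the same orientation/E2A odds; it
is the direct embodiment of the sampling model those tests assume, and is
what the calibration and power checks use.

**ICeChIP.** Input coverage is uniform at the chosen depth; IP coverage at
position *p* is Poisson with mean `depth × planted_HMD(p) × capture(target)`;
barcode counts are Poisson around `input count × capture`. Default standards:
the five methyl-lysine nucleosomes with target capture 1.0, off-target 0.05,
and 10⁵ input barcode reads per standard (typical spike-in sequencing depth).
A `noise="none"` mode returns expectations exactly for closed-form checks.

## Analysis choices

* **Classification rules** (in order): no Vκ/Jκ-overlapping reads →
  `no_expression`; V–J junction reads on both alleles, or junctions plus Igλ
  expression → `recomb_two_or_lambda`; junctions on exactly one allele →
  `recomb_one_allele`; biallelic germline Jκ (≥ 3 reads per allele, either
  promoter) with an RSS-motif-bearing J-flank read and zero junctions →
  `poised`; anything else → `uncategorized`. RSS defaults: heptamer CACAGTG,
  nonamer ACAAAAACC, one mismatch tolerated. Thresholds (≥ 1 junction read,
  ≥ 3 germline reads per allele, ≥ 5 reads for "expressed", ≥ 5 Igλ reads)
  are configuration with those defaults.
* **Allele calls** pool SNPs with total haplotype-matching coverage ≥ 30; a
  segment is single-allele when the minor haplotype holds ≤ 10% of pooled
  bases — the tolerance absorbs sequencing error without admitting genuine
  biallelic transcription. Biallelic calls count against monoallelism in all
  summary fractions. Cells with a single informative gene are included in the
  locus-wide denominator by default (`include_single_gene_cells=False`
  restricts to ≥ 2).
* **Splice filter** is applied per cell (≥ 10 supporting reads per
  segment-pair edge, pooled across junction coordinate variants); a pooled
  multi-cell mode is just concatenating junction lists before aggregation.
  Interpolation is per edge — every annotated Vκ strictly between the two
  spliced segments — not per component hull. Antisense edges (CT..AC on the
  reference) form separate strand-tagged components. Transcript "span" is
  genomic extent; exonic length is reported alongside. Junction-to-segment
  annotation tolerates an 8 bp flank (antisense splice points sit 4 bp outside
  segment edges).
* **Bias tests.** Expression events are (cell, segment) pairs; opportunity
  totals are class size × cells. Orientation: Fisher on away vs into
  (disjoint) and away vs all (the figure-style companion). E2A: the displayed
  fractions are E2A-associated vs all Vκ, but the Fisher test and odds ratio
  use the disjoint E2A vs non-E2A partition — testing a class against a pool
  containing it is structurally conservative (the shared events cancel most
  of the margin variance) and compresses the odds ratio, whereas the disjoint
  test is exactly calibrated and recovers the planted odds. The Fisher test
  itself is two-sided by the point-probability method with exact integer
  hypergeometric weights (tie handling is exact, not floating-point).
* **HMD** is computed per bp and reported unclipped (sampling noise can push
  it above 100%; clipping would bias recovery). Window and region summaries
  use the ratio of mean coverages rather than the mean of per-bp ratios: a
  Poisson input count in each denominator inflates the mean of ratios by
  ≈ depth/(depth−1). Metagene bins average the per-bp track with exact
  base-pair overlap weighting; 100 bins over the gene extended by 10%
  cushions, reversed for minus-strand genes; the TSS window is the
  −10%..+10% of-gene-length interval around the start, equivalently the
  first ≈ 17 bins of the extended profile.
* **MAE enrichment** consumes a local TSV snapshot (no live database);
  `predicted_monoallelic` is carried as a distinct status and excluded from
  the measured-MAE fraction by default. The background set is a required
  input, never inferred.

## Problem sizes

The packaged checks run cohorts of 100–500 cells for classification,
topology, and calibration properties, 2000 cells for locus-wide allele
recovery, 1000 null cohorts for test calibration, and exhaustive enumeration
of all 2×2 tables with total ≤ 40 against an independent Fisher oracle —
sizes at which the binomial error of every recovered parameter is several
times smaller than its acceptance band.

## What passing tests do and do not show

The generator reproduces the statistical structure the analyses assume —
haplotype-consistent SNP bases, canonical junction motifs at planted splice
points, TAD-truncated run lengths, Poisson sequencing noise — so passing
tests demonstrate that the pipeline recovers planted truth under that model.
Real data adds what the generator deliberately omits: alignment artefacts and
mapping bias between haplotypes, PCR duplicates and UMI structure, indels,
overdispersed coverage, ambient RNA, incomplete annotation, and cell states
outside the four modelled ones. Results on real libraries depend on upstream
alignment quality in ways these tests cannot certify.

## Known limitations

* The toy locus is ~10% of the real locus's extent with regular segment
  spacing; absolute spans and distance profiles scale accordingly.
* Unit inference assumes junction support between consecutive transcribed
  segments; sparse junction coverage fragments a unit into components rather
  than joining them (conservative).
* Strand of a singleton (junction-free) unit is taken from the segment's own
  orientation; antisense singleton transcription is not detectable from
  coverage alone.
* The classifier does not model productive/non-productive rearrangements,
  Vκ–Vκ recombination, or receptor editing.
* `filter_fragments` requires both mates present in the input; orphaned mates
  of otherwise-proper pairs are dropped.
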