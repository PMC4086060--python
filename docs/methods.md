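# Methods

This note records how the profiler is defined, the choices made where the
procedure admitted more than one reasonable definition, and what the
synthetic fixtures do and do not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open.  BedGraph is natively so;
WIG positions are 1-based and converted on read (a fixedStep block with
start *s*, step *p*, span *v* places its k-th value on
[s−1+(k−1)p, s−1+(k−1)p+v)); the annotation table is *declared* 0-based
half-open (`docs/formats.md`).  Keeping one convention internally removes
a whole class of off-by-one errors at block boundaries.

Overlapping intervals within one signal file are a hard parse error, not
last-wins: silent overwriting would hide corrupted or double-counted
input.  Overlap detection is done against a merged-coverage list per
chromosome, so its memory grows with the number of coverage gaps, not
with the number of data lines, and the chunked reader's memory contract
survives unsorted input.

## Anchors and blocks

With anchors a₁<…<aₙ, the n+1 blocks are traversed 5'→3' in the
transcribed direction; the two flank blocks extend outward by their
represented extent (window_count × window_size for the absolute method, a
configured `flank_extent` for the relative method) and are truncated at
position 0 (chromosome start).  Chromosome lengths are not part of the
annotation format, so no right-edge truncation is applied; windows beyond
the data simply have no coverage and register as missing.

Neighbor-derived anchors (n = 4 or 6) use the nearest annotation on each
side, any annotation type counting as a candidate.  Three edge policies:

- **Overlapping neighbor** — its proximal boundary is clamped to the
  feature boundary, making the intergenic block zero-length (all its
  windows missing for that feature); the side is labeled `overlap` for
  subgrouping and the `exclude_overlapping` filter.
- **Nested annotation** (fully inside the feature) — never returned as a
  neighbor and never supplies anchors, but marks the feature as
  overlapping for the filter.
- **Missing neighbor** — the anchors on that side collapse to the
  chromosome boundary, truncated at the block's represented extent, so
  the feature still contributes everywhere else rather than being dropped
  (dropping would bias small groups toward chromosome interiors).

Because clamping and collapsing can make adjacent anchors coincide,
anchor tuples are validated as non-decreasing rather than strictly
increasing; a zero-length block is well-defined (all windows null).

Exon mode takes the boundaries of the first, middle and last exons in
transcribed order, the middle of *k* exons being exon ⌈k/2⌉ ("middle" has
no unique definition; this one is fixed and documented).  Features with
fewer than three exons are excluded and logged.  Coordinate mode with one
reference point uses the interval midpoint ⌊(start+end)/2⌋ — exact for
1 bp summit records, the common input for that mode.

## Window placement

Absolute split blocks tile the feature 5'→3' with Wf = ⌈L/w⌉ windows (the
last possibly partial) and keep the first ⌈c·f⌉ and last c−⌈c·f⌉ of
c = min(Wf, Wl) under split fraction f (default 0.5; the extra window of
an odd c goes to the 5' side — an arbitrary but fixed tie-break).
Partial terminal windows are kept and weighted by their covered bases;
discarding them would systematically bias short features.  Relative
blocks use equal fractional-width bins; extraction weights bases by their
(possibly fractional) overlap with the bin.

Minus-strand features are handled by expressing each block in transcribed
offsets and mapping them onto the genome right-to-left.  This makes the
pipeline mirror-symmetric by construction: mirroring the genome
(x → L−x, strands flipped, values preserved) leaves every per-feature
transcribed profile — and hence the aggregate — unchanged, which is the
same statement as "reversed" when windows are indexed genomically.

## Estimation and aggregation

The within-window estimator is the coverage-weighted mean, with uncovered
bases excluded from the weighting rather than zero-filled: zero-filling
conflates "no data" with "no signal", and the distinction is exactly what
the proportion track exists to expose.  (A `missing_as_zero` switch is
available for tracks where absence genuinely means zero.)  Per window the
aggregate takes the configured statistic over contributors only; SD uses
the n−1 denominator and SEM = SD/√n, both reported only from two
contributors; the proportion divides the contributor count by the *full*
post-filter group size, so members whose block is unrealized (overlapping
neighbor, short feature, coverage gap) pull it below one.

Smoothing is a centered sliding mean over `smoothing` windows applied to
the aggregate statistic only — never to individual profiles, and never
across block boundaries, since consecutive windows of different blocks
are genomically discontinuous.  For even spans the center is left-biased
(⌊s/2⌋ left, s−1−⌊s/2⌋ right); edges average over the in-range windows.

## Streaming

Datasets are never loaded whole: window geometry is indexed once in
per-chromosome interval trees and each signal interval deposits
value×overlap into the (feature, window) cells it touches.  Deposits per
cell arrive in file order for any chunk limit, so the accumulated sums —
and therefore the output TSV bytes — are identical whether the reader
buffers 1 line or the whole file.

## Synthetic fixtures and what passing means

The generator emulates the qualitative shapes of common chromatin marks:
a 3'-accumulating body ramp (Set2-pathway-like co-transcriptional marks),
a triangular TSS peak (promoter-restricted variants), exon-enriched
signal, and uniform background, with optional i.i.d. Gaussian noise per
emitted interval, coverage gaps, controlled neighbor orientations and
controlled overlapping pairs.  Defaults (8 genes of 0.8–2.4 kb with
0.4–0.9 kb gaps on one chromosome) mimic a compact, yeast-like gene
density, where flank contamination and orientation effects are at their
strongest.  Noise-free patterns admit exact per-window expectations,
evaluated per base directly from the pattern definition — independent of
the parsers, the extraction and the accumulator they are used to check.

These fixtures establish arithmetic correctness (layout, extraction,
statistics, invariances), not biological fidelity: real tracks have
correlated noise, mappability artifacts, unannotated transcription and
assembly-specific quirks that no test here represents.  Test problem
sizes (genomes of tens of kb, groups of 4–24 features, 50 randomized
oracle fixtures) were chosen as the smallest instances that exercise
every code path, including multi-block layouts and both strands.

## Known limitations

- BigWig and BAM input are not supported; inputs are text BedGraph/WIG.
- No signal normalization: datasets are assumed normalized upstream.
- One annotation row is one feature; transcript isoforms are not
  collapsed, and neighbor search does not distinguish annotation types.
- No clustering of individual profiles; the individual TSV is meant to be
  consumed by external heatmap/clustering tools.
- Whether smoothing should cross block boundaries and whether the
  within-window estimator should weight by probe rather than base
  coverage are genuinely open conventions; the choices here (no, and
  base-coverage) are documented above and applied consistently.
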