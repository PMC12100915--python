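# Methods

## Scope and model

`cffrag` extracts fragment-level features from paired-end cfDNA alignment
data. The unit of analysis is the *curated fragment*: for an inward read
pair on one contig, the interval from the forward (plus-strand) read's
start to the reverse (minus-strand) read's end, in 1-based inclusive
coordinates (`length = end − start + 1`). This definition is exact for
sequence-through pairs whose forward read carries an aligned 3′ adapter
overhang, whereas the outermost-boundaries length (kept only as the
`problematic_length` diagnostic) over-counts such pairs by the overhang.

### QC and curation policy

QC rejects a pair if **either** mate violates a rule, with reasons
evaluated in fixed order: unmapped → mapping quality < 30 → duplicate →
secondary → supplementary → proper-pair (only when explicitly enabled).
Proper-pair filtering is off by default: aligners assign the flag under a
unimodal insert-size model, and cfDNA's di-/tri-nucleosome peaks fall
outside it, so requiring the flag depletes long fragments.

Curation then rejects, in order: mates on different contigs
(`SEQNAME_DISCORDANT`); missing or same-strand orientation (`NO_STRAND`);
non-inward geometry (`NOT_INWARD`); out-of-bounds coordinates
(`OUT_OF_BOUND`). "Inward" is operationalized as *forward-read start ≤
reverse-read end*; this test also subsumes the curated-start-exceeds-end
case, so `OUT_OF_BOUND` in practice covers only contig-boundary
violations. Accounting is exact: `pairs_in = passing + Σ rejections`.

Alignment spans use reference-consuming CIGAR operations (soft clips
excluded). Orphaned records (mate absent from the file) are counted and
reported, never silently dropped. Region queries resolve out-of-window
mates through the index so a pair qualifies whenever either record
overlaps the window.

### Lengths, motifs

Lengths are tallied in a dense integer histogram over a retention window
(default 50–450 bp; exclusions counted so totals conserve). Range
fractions default to the 50–99 / 100–150 / 151–220 / 300–380 bp ranges,
inclusive on both bounds. Cross-sample profiles use element-wise medians
(even counts: mean of the central pair); the median profile need not sum
to 1.

Motifs are read from the **reference genome** at fragment coordinates
(side `u`/`s`/`e`/`d`, width k), reported on the genomic forward strand;
an optional flag reverse-complements `e`/`d` motifs into the 5′-centric
convention used by some end-motif literature. Windows beyond contig ends
are N-padded; motifs containing N are excluded and tallied separately so
each table has exactly 4^k rows. Pearson correlation between fraction
vectors returns NaN (never raises) on zero-variance input.

### Mutation overlap and SBS profiles

For each fragment × a priori locus, the base observed by each mate is read
by walking the CIGAR to the reference position (bases below quality 20
masked; deletions yield no observation). Categories: CO (both cover, both
alt), SO (exactly one covers, it is alt), DO (both cover, exactly one
alt), REF_ONLY (coverage, no alt), NO_COVER (no read base at the locus —
possible for fragments longer than twice the read length, whose middle is
unread). A both-cover disagreement that does not involve the alt base is
REF_ONLY, not DO: DO is defined specifically as conflicting evidence about
the variant allele.

Per-locus support excludes DO fragments from `alt_count` by default (DO is
a noise gauge); a flag includes them. The de novo pileup counts one
observation per fragment per position: where mates overlap they must
agree, otherwise the observation is discarded (double-count guard).

SBS profiles use the standard 96 pyrimidine-centric contexts in COSMIC
column order; purine-reference loci are reverse-complemented. Profiles are
fragment-weighted (each supporting fragment contributes 1) and stratified
by ALL / CO / SO / DO / CO+SO; the DO-removed profile is ALL − DO. Cosine
similarity is the usual normalized dot product, NaN for zero vectors.

### Copy number (deliberately minimal)

Midpoint assignment into fixed-width half-open bins (default 1 Mb, last
bin truncated; a midpoint on a boundary goes right), so counts conserve
fragments exactly. GC correction: rank-based GC deciles with tie merging
(equal GC values always share a stratum; the stratum count shrinks when
fewer than 10×3 usable bins are available), `corrected = raw ×
global_median / stratum_median`, strata with under 3 bins are excluded.
States: `log2(corrected / autosomal median)` thresholded at ±0.2. No
segmentation, mappability, blacklist or ploidy modelling — the module
exists to make state calls and gene-level mutation annotation testable,
and is documented as non-equivalent to segmentation-based callers.

### Summary metrics

Computed over primary records only, so fractions are per sequenced read:
unmapped fraction (of primary), mitochondrial fraction (of mapped
primary; contig set {chrM, MT} configurable), mismatch fraction
(Σ edit-distance tags / Σ aligned bases; reported absent when no tag
exists), per-read GC (ambiguous bases excluded from the denominator), and
mean coverage (Σ aligned bases / Σ contig lengths, mitochondrion
includable by flag). Downsampling keeps or drops whole templates by a
seeded hash of the query name: deterministic, pair-preserving, and
composable with coverage targets via the measured mean coverage.

## The synthetic data generator

The generator emulates the observable structure of cfDNA sequencing data:
a small multi-chromosome reference with a mitochondrion-like contig
(per-contig GC placed at exact counts, so realized GC matches the target
to one base); fragment lengths from a Gaussian mixture (default 0.7
N(167, 10) + 0.2 N(334, 20) + 0.1 N(90, 15), floored at 30 bp) — a
*testing device*, not a claim about cfDNA biology; uniform fragment
placement modulated by rejection sampling for start-base motif bias and
copy-number region multipliers; paired 150 bp reads with consistent flags,
CIGARs, mate fields and NM tags; optional 3′ forward-read overhangs on
sequence-through fragments (reference bases standing in for adapter that
happens to align, extended past the fragment end even when this slightly
exceeds the nominal read length); per-base substitution errors; and spiked
variants whose covering fragments carry the alternative allele with
probability VAF, with a configurable fraction of both-cover fragments made
discordant.

Two choices depart from naive sampling, both so that tests can assert
exact recovery rather than statistical agreement:

- **Artifact labels are planted at exact counts** `round(rate × n)` on a
  seeded permutation (duplicate, low-MAPQ = 5, secondary, unmapped mate,
  discordant-chromosome mate, outward strand-swap). Spiked-variant alt
  assignment remains binomial, since allele fractions are inherently
  sampled quantities.
- **Outward labels are restricted to fragments ≥ 2× read length.** An
  outward pair is emitted by swapping the strand assignments of an inward
  pair; when the two read spans overlap, the swapped pair is geometrically
  indistinguishable from an inward pair, so only fragments long enough for
  the swap to be detectable receive the label. This keeps planted label
  counts exactly recoverable by curation.

Deterministic placement is also used for the mitochondrial fraction
(exactly `round(mito_fraction × n)` fragments on chrM), so the summary
metric can be checked for exact equality.

What the generator does **not** model: sequencing-by-synthesis error
profiles and quality variation (base qualities are constant Q37),
UMI/adapter library structure, alignment ambiguity from repeats (every
read aligns at its true position with an all-match CIGAR), methylation
conversion, and real nuclease-derived end-motif structure. Passing tests
therefore demonstrate the correctness of the feature extraction logic
under controlled conditions, not robustness to aligner artefacts or real
biological variation.

Identical configuration (including seed) reproduces byte-identical
reference and alignment files; seeds feed three independent streams
(reference, fragment simulation, emission).

## Statistical behaviour of the synthetic checks

Two calibration checks are intrinsically noisy and are documented as such:

- The empirical argmax of the length histogram for a discretized
  N(167, 10) component is a near coin flip between 166 and 167 even at
  5 × 10⁴ fragments (expected count gap at the mode ≈ 7 vs counting noise
  ≈ 53); a 3σ-stable mode would need ~2.5 × 10⁷ fragments. Correctness of
  curation is instead established by the exact per-fragment truth
  comparison, which is noise-free.
- Per-locus VAF recovery at 3σ across 20 loci is a family of 20
  simultaneous tests with ≈ 5% family-wise failure probability by
  design; the recovered per-fragment categories are additionally checked
  for *exact* equality with the planted truth, which isolates generator
  sampling noise from recovery errors.

## Problem sizes and defaults

Tests and the acceptance script run at 2.5 × 10³–10⁵ fragments on
0.03–50 Mb synthetic genomes — sizes chosen so every statistical oracle
(binomial / Poisson 3–4σ bands) has adequate power while a full run stays
comfortably on one CPU. Key defaults: MAPQ ≥ 30; retention window
50–450 bp; base quality ≥ 20 for allele observations; bin size 1 Mb with
gain/loss thresholds ±0.2; read length 150 bp; overhang length 10 bp.
All are configurable at the API and CLI level.
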