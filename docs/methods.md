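# Methods

This note documents the models, parameter defaults, and numerical choices
behind `asmkit`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open; 1-based inclusive
coordinates exist only at file boundaries (VCF, sync, AGP, RepeatMasker
`.out`), each converted exactly once by its reader/writer. Interval merging
follows `bedtools merge -d` semantics (gap ≤ `max_gap` merges, so abutting
intervals merge at `-d 0`) and fraction-intersection follows
`bedtools intersect -f` (an interval of the first set survives when the
union of the second covers at least the given fraction of its length, with
the boundary inclusive). Both are asserted against per-base brute-force
oracles in the test suite.

N50 is the contig length at which descending cumulative lengths reach half
the assembly size; NG50 replaces the assembly size with an external genome
size estimate. Because published totals depend on a genome-size constant
that is rarely printed, the estimate is a required parameter rather than a
default. When half the estimate exceeds the assembly total, NG50 is
undefined; we report 0 with a warning so that ranking code can treat it as
worst rather than crash. Gap bases are runs of `N`/`n` of any length —
anchoring gaps are exact 10 kbp spacers, so no minimum run length is
needed.

## Misassembly detection

The detector targets inter-chromosomal chimeric joins, which produce two
independent signatures:

1. **Variant density.** Raw long reads aligned across a chimeric join pile
   up residual differences. We count variant sites with QUAL strictly
   greater than 10 in non-overlapping 10 kbp tiling windows and flag
   windows with strictly more than 1 variant per kbp (i.e. > 10 per full
   window; the final partial window of a contig scales the threshold by
   its true width). Tiling rather than sliding windows: the per-window
   density report this emulates is a tiling computation, and sliding adds
   nothing at the 20 kbp merge scale.
2. **Physical coverage.** Spanning (outer-span, fragment-level) coverage
   of a large-insert (40 kbp) mate-pair library, counting only concordant
   pairs: both ends on one contig, convergent orientation, outer span
   within 0.5–2× the library insert. No genuine fragment spans a chimeric
   join, so coverage dips toward zero there. Regions below 20× are
   flagged; the first and last 200 kbp of each contig are masked because
   coverage decays toward contig ends for purely geometric reasons.

Each signal is merged within 20 kbp, and merged variant regions covered at
least 80% by merged low-coverage regions form the dual-signal candidates.
Adjudication against two marker maps then applies three rules: a map-order
conflict (a contig whose ordered hits switch linkage group) is always
accepted, with the conflict interval being the gap between the nearest
hits of different groups; a dual-signal region overlapping map conflicts
attaches its evidence to them — and when both maps conflict over the same
event their intervals are *intersected*, since the two maps jointly narrow
the breakpoint; a dual-signal region containing no markers from either map
is accepted on sequence evidence alone; any other dual-signal region is
rejected as vouched-for by the maps. The conservative middle case (markers
from only one map, concordant) is rejected — sequence-only acceptance is
reserved for genuinely marker-free regions.

Break positions are the legal position nearest the candidate midpoint,
where "legal" excludes the open interior of any transcript alignment and
of any *single* repeat record (the boundary between two abutting records
remains legal), leftmost on ties. Splitting k contigs at k breakpoints
yields exactly k additional contigs and conserves sequence; `.1`, `.2`
suffixes name the pieces deterministically.

## Anchoring

Assignment is by plurality of marker hits with a two-marker minimum;
contigs with two or more qualifying linkage groups are "problem contigs"
(recorded, still assigned to the plurality group — exact ties are left
unanchored instead). Ordering uses the median map position of a contig's
hits; orientation is the sign of the Spearman rank correlation between
contig position and map position, `ambiguous` when all map positions tie
(low-resolution maps place many markers at one genetic position).
Ambiguous contigs are written forward with AGP orientation `?`. This is
the simplest monotone criterion consistent with the anchoring tools it
emulates; those tools' internal scoring is not re-specified here.
Pseudomolecules join contigs with fixed 10 kbp `N` gaps (AGP gap rows of
type `map`), so gap count per group is placements − 1 by construction, and
the AGP plus the component contigs reconstruct the anchored FASTA
byte-identically.

## Candidate-assembly evaluation

BAC-end pairs are classified from their best hits after an E-value <
1e-150 filter: `unaligned` (no end passes), `1` (one end), `4` (different
contigs), `2` (same contig, convergent, outer span within 50–400 kbp for
~150 kbp clones — the span band is configurable since no published bounds
exist), else `3`. Rank averaging uses dense ranks per library (higher
score = rank 1, ties share a rank), making the result invariant to any
monotone per-library transform. The PCA standardizes each metric column
(mean 0, variance 1 with ddof = 1) and decomposes by SVD; each component's
sign is fixed so its largest-magnitude loading is positive, and constant
columns are dropped with a warning. Likelihood scores, core-gene counts
and exon-bp totals are consumed as numbers; computing them is out of
scope.

## Pool-seq sex scan

Sync counts treat the deletion column as a fifth allele and ignore `N`.
Analyses reduce each site to its two most frequent alleles over the two
pools combined. The per-site FST is the classical pooled-heterozygosity
form with the n/(n−1) sampling correction on read depth:
π_k = n_k/(n_k−1)·2p_k(1−p_k), π_T likewise on the summed counts, and
F_ST = (π_T − (π_a+π_b)/2)/π_T, defined as 0 for a monomorphic combined
site and clamped to the [0, 1] contract (the correction can push the raw
estimate slightly negative for undifferentiated pools). Pools under 10
reads are uncallable. Exact numeric parity with any particular external
pool-seq tool is a non-goal; the estimator is stated here and verified
against an independent hand evaluation.

A site is *sex-patterned* when the homogametic pool's minor-allele
frequency is ≤ 0.1 and that same allele sits in [0.3, 0.7] in the
heterogametic pool. The criterion — not this particular threshold triple —
is the method; all three numbers are parameters with these defaults,
chosen as the loosest values that still mean "nearly fixed" and
"intermediate". Windowed tracks (10 kbp tiling) report mean FST and
sex-patterned counts; region calling takes maximal runs of windows with
count ≥ 10, tolerating single-window dropouts, requiring ≥ 5 qualifying
windows, with boundaries at the outermost qualifying windows.

## Synthetic data: what it emulates, and what it does not

The generators are deterministic under their seed and produce: random-base
chromosomes (optionally with interspersed repeat copies at per-copy
divergences and terminal satellite arrays); chimeric contigs built by
cutting chromosomes into segments (≥ 500 kbp) and re-chaining them
round-robin so neighbouring segments always come from different
chromosomes, conserving total bp and recording every junction; variants as
a Poisson background (0.05/kbp) with junction halos (±20 kbp at 3/kbp) and
a 10% low-quality fraction straddling the QUAL filter; mate pairs sampled
from the *true* chromosomes (40 kbp ± 4 kbp inserts, 10,000 pairs ≈ 40×
physical coverage on the 10 Mbp default genome) and lifted onto the
contigs, so spanning coverage dips at junctions arise mechanically, not by
decree; markers every ~40 kbp (RH-style) and with a second spacing
(RAD-style) with monotone map positions; pooled counts with a truncated
Beta(0.5, 0.5) on (0.05, 0.95) shared background frequency (an arbitrary
neutral-SFS-like choice, documented as such), homogametic fixation and
heterogametic Beta(50, 50) inside the declared region, Poisson(40)
coverage and binomial sampling; and BAC-end pairs at 100–200 kbp spans
with truth classes derived from the same lift-over.

Not emulated: read-level data (no FASTQ, no sequencing-error model), real
repeat landscapes (junctions in real assemblies sit in nested repeats that
*cause* the misassembly; here they are independent), mapping ambiguity
(every placement is exact), reference bias in pool alignments, and
structural events other than inter-chromosomal joins (no inversions).
Passing the recovery tests therefore shows the *logic* of the detectors is
correct under their stated signal model — clean signals give clean calls —
not that their thresholds are optimal for any particular real library.

Default study conditions: the misassembly scenario uses a 10 Mbp genome
(five 2 Mbp chromosomes) with 10 junctions, scored over seeds 1–5; the
sex scenario uses a 5 Mbp chromosome with a 1 Mbp region (2.0–3.0 Mbp),
sites every 200 bp, scored over the same seeds with XY and mirrored ZW
configurations. These sizes keep a full validation run under a minute
while leaving every rate (coverage, marker density, variant density)
identical to the genome-scale setting it models.

## Reporting

Percent changes always use the old value as denominator and round half-up
to one decimal (two for polishing percentages); rounding is centralized in
one function so printed-figure reproduction is deterministic. Zero old
values report NA rather than infinity. Negative changes keep their sign in
tables and render as "decreased by N (P%)" in prose. The bundled
reference tables for the tilapia assembly upgrade store only raw printed
inputs (sizes, counts); every derived figure is recomputed.

## Known limitations

- The adjudicator assumes exactly two maps; more maps would need a vote
  rule that is currently not defined.
- Orientation by rank correlation is undefined for single-marker contigs
  (they require ≥ 2 markers to anchor at all) and ambiguous under tied map
  positions; no attempt is made to rescue orientation from neighbouring
  contigs.
- Physical coverage is computed at base resolution in memory
  (4 bytes/base/contig), fine for contigs up to hundreds of Mbp but not
  optimized beyond that.
- The FST estimator ignores pool sample sizes (number of individuals),
  using read depth alone, as pooled-sequencing conventions do when pool
  sizes are large relative to depth.
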