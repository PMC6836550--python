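# Methods

This note documents the models and procedures implemented in `cytowgs`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical/design choices made where the underlying
clinical practice leaves them open.

## Coordinates and printed sizes

Clinical CNV tables print a region `chrN:start-end` with size
`end − start`.  All intervals in the package are therefore treated as
half-open-equivalent, and `GenomicInterval.length()` is `end − start`
with no `+1` anywhere.  ISCN microarray strings
(`arr[GRCh37] 2p21p22.1(39053852_42501893)x3 dn`) are parsed with both
`_` and `-` accepted as coordinate separators; band tokens are kept
verbatim as labels and only the leading chromosome is interpreted.
Sizes render at three significant figures with trailing zeros dropped
("3.45 Mb", "502 kb", "15 Mb").

## SV merging and the filter cascade

Two pseudo-callers model the complementary behaviour of read-depth and
discordant-pair SV calling.  Their records merge when they have the same
type on the same contig and either both breakpoints lie within `bp_tol`
(default 200 bp) or reciprocal overlap is at least 0.7; clustering is
single-linkage (transitive), and the cluster representative is the
member with the highest read-pair support (ties: smallest start).  The
defaults are conventional SV-database merge settings and both are
exposed.

Frequency databases are built by the same merge rule across samples; a
cluster's allele frequency is distinct contributing samples over total
samples indexed.  Query matching reuses the pair criterion against the
cluster representative, so breakpoint jitter within `bp_tol` still
matches.

The filter cascade applies, in order: **size** (intergenic kept iff
length > 10 kb, intragenic iff > 2 kb; intragenic means ≥ 1 bp overlap
with a panel gene), **quality** (pair-only calls need ≥ 6 discordant
pairs; depth-only calls need ≥ 5 kb; calls seen by both callers pass),
**frequency**, and **decoy** (contigs `hs37d5`, `NC_007605`, or any
label containing "decoy").  Each removed call is tallied at its first
failing stage, so `Σ tally + retained = input` and the filter is
idempotent.  Frequency boundaries are deliberately asymmetric at
equality — population AF ≤ 0.005 is retained, internal AF must be
strictly < 0.01 — because the written operators ("< 0.5 %", "< 1 %") are
ambiguous at equality; both are configurable.  The panel-rescue lane
keeps any call with a breakpoint junction inside a panel gene regardless
of size (quality/frequency/decoy still apply), and the union with the
genome-wide lane is duplicate-free.

## Array emulation and platform comparison

The CGH-style export places synthetic probes every `spacing` bp (default
18 kb, a typical 180K-array median spacing) with log2 ratio 0 outside
calls and `log2(CN/2)` inside; copy 0 is floored at −3 to stay finite
and plottable.  The document is a self-describing UTF-8 XML dialect
(probes plus a segments block) and is deterministic for fixed input.  It
is an emulation for visualization and testing, not a claim of
compatibility with any proprietary array format.

Array CNV calling uses exactly the stated clinical rule: maximal runs of
at least three consecutive probes beyond −0.65 (loss) or +0.35 (gain).
Runs are broken by chromosome boundaries and by any in-range probe — no
gap tolerance and no segmentation algorithm is emulated beyond this
rule.  In the WGS-vs-array comparison an array call counts as found iff
it overlaps a WGS record of matching direction by at least 1 bp
(loss↔DEL, gain↔DUP); a loss overlapping a gain is not a confirmation.
The overlap criterion is this module's documented choice.

## Derivative-chromosome reconstruction

A rearrangement cluster is reconstructed over a breakend graph.  Nodes
are segment boundaries obtained by cutting each involved chromosome at
every junction end and CNV boundary; edges are reference adjacencies and
junctions.  A breakend `(chrom, pos, side)` retains the reference bases
to its left (`L`) or right (`R`).  Explicit junctions come from mate
breakend (BND) records; interior deletions imply an `(s,L)–(e,R)`
junction, tandem duplications an `(e,L)–(s,R)` self-junction, and
inversions two junctions — but an implied junction is suppressed when
terminal (reaching a contig end) or when its boundary coincides with an
explicit breakend, which then describes the true geometry (this is what
distinguishes DEL-INV-DEL from two independent deletions, and an
inserted from a tandem duplication).

Each segment carries a multiplicity on the derivative haplotype
(1 + duplications − deletions covering it, floored at 0).  The walk
starts at a telomere (or, when telomeric segments are lost, at the first
surviving segment), follows an unused junction whenever the current
segment end carries one and the reference adjacency otherwise, consumes
each junction once, and may traverse a segment once per multiplicity.  A
walk that returns to its start is a ring; a junction pointing at a
missing or exhausted segment yields a partial structure flagged
incomplete.  Reconstruction conserves copy number: every reference base
of the cluster region appears in the output with multiplicity equal to
its derivative copy number.

Topology classification is a deterministic rule table over the
reconstructed structures: circular → ring; two structures exchanging
terminal segments of two chromosomes → reciprocal translocation; one
chromosome's backbone with interior foreign segments → insertional
translocation; a foreign terminal segment on one end only → unbalanced
translocation; intrachromosomal patterns are labelled from the counts of
deleted runs, duplicated runs and inverted segments (simple-DEL,
DEL-NML-DEL, DEL-INV-DEL, tandem-DUP, DUP-NML-DUP, otherwise
other-complex).  Structures are canonicalized (a structure equals its
reverse-complement presentation) so labels are invariant to record order
and mirror presentation.

## Breakpoint-junction analysis

`analyze_junction` aligns a junction sequence against the two reference
flanks: after orientation normalization, the maximal matching prefix
(side A) and suffix (side B) either overlap — the overlap is
microhomology — or leave a gap, the inserted sequence.  Microhomology is
exact identity only; no mismatches are tolerated, and microhomology and
insertion are mutually exclusive at one junction by construction.
Maximal insertion substrings of ≥ 10 bp found exactly (either strand)
within the cluster's breakpoint-flank sequences are reported as
templated; 10 bp makes a chance 4-letter match improbable (4¹⁰ ≈ 10⁶)
within a ±1 kb search context.  Mechanism inference applies rules in
order: recurrent + repeat-flanked → NAHR-like (repeat annotation is an
input flag, since repeat context is external knowledge); any templated
fragment → replicative-like; all junctions with microhomology ≤ 4 bp and
non-templated insertion ≤ 20 bp → NHEJ-like; else unclassified.  The
NHEJ thresholds turn qualitative descriptions ("no microhomology, short
random insertions") into fixed, configurable numbers.

## ROH and UPD

The zygosity track is the fraction of homozygous high-quality SNVs per
fixed 10-kb window; windows with fewer than 5 qualifying sites are
flagged missing.  The heterozygous complement is exposed alongside, so
both the "fraction homozygous" plotting convention and the heterozygous
zygosity-ratio definition are served by one track.

The RoH caller takes maximal runs of windows with homozygous fraction
≥ 0.95 and keeps runs spanning ≥ 1 Mb.  Three tolerances mirror standard
ROH-caller practice (true autozygosity is interrupted by genotyping
noise, not ended by it): missing windows bridge a run; a below-threshold
window with ≤ 1 heterozygous site continues a run; and runs separated by
≤ 100 kb are merged before the length filter.  With typical WGS densities
(~1 het per 1.5 kb, so ~7 hets per normal window) the probability that a
normal window passes these tolerances is below 1 %, so leakage across a
true boundary is a few kilobases at most, while a single mis-genotyped
site inside a megabase-scale isodisomy no longer splits it.  All
thresholds are parameters; none is prescribed by the underlying
clinical description beyond the 10-kb window.

UPD typing with a full trio counts sites where the child shares no
allele with one parent as evidence for uniparental inheritance from the
other; ≥ 20 informative sites are required, and strong evidence in both
directions yields no call with a warning.  Isodisomy additionally
requires overlap with an RoH segment; biparental incompatibility without
homozygosity is heterodisomy; evidence confined to a subinterval
(< 90 % of the chromosome) makes the call segmental.  With a single
parent, an RoH segment whose homozygous child alleles all match that
parent is reported as consistent with that parent's isodisomy — the
single-parent situation that arises in practice when only one parent is
available for testing.

## STR genotyping

Alleles are sized exactly from reads in which the full repeat tract is
delimited by flanking sequence on both sides; expansions longer than the
read are estimated from in-repeat reads (≥ 90 % motif, no 15-bp flank
anchor) by inverting the uniform read-sampling model:
`tract_bp ≈ read_len + n_irr · read_len / allele_depth`, with
`allele_depth = depth/2` for a heterozygote — the only reading under
which the estimator is the exact inverse of the generator's sampling
model in expectation.  The in-repeat path engages when more than one
in-repeat read is seen (a single such read can arise from a borderline
normal allele).

Two geometric facts shape the design.  First, a read of length *r*
delimits a tract of length *t* only if both junctions fall inside it, a
window of `r − t − 1` start positions; at 15× per haplotype and
`r = 151`, a 138-bp tract (46 CAG units) leaves roughly one such read
expected, so exact sizing near the read length is coverage-limited and
consumers needing a deterministic answer should aggregate over
replicates (the acceptance script reports the consensus call over 25).
For the same reason, classification anchors (15 bp of exact flank match)
are deliberately decoupled from counting: a read may delimit the tract
with as little as one flanking base on each side and still be counted,
because synthetic reads are error-free and alignment-free.  Second,
reads overlapping a long tract with under ~15 bp of flank are classified
in-repeat, which inflates the in-repeat window by ~2 × 14 bp and biases
the estimator upward by ~4 % for a 699-bp tract — inside the stated
±10 % accuracy, and left uncorrected to keep the estimator exactly the
stated formula.  Only exact motif copies are counted; interrupted or
impure repeats are a documented limitation.  The bundled 17-gene catalog
carries approximate GRCh37 coordinates and motifs; pathogenic thresholds
are catalog configuration, not clinical assertions.

## Mosaic aneuploidy

A chromosome duplicated in a fraction *f* of cells multiplies its
expected depth by `1 + f/2`; the estimator inverts the median-depth
ratio over a median/MAD autosomal baseline (sex chromosomes and the
tested chromosome excluded) as `f = 2(r − 1)` for gains and `2(1 − r)`
for losses, clamped to [0, 1].  Median/MAD statistics keep planted focal
CNVs from moving the baseline.  The genome-wide scan flags a chromosome
when the shift is both statistically clear (|z| ≥ 5, z from the standard
error of a median under MAD-estimated noise) and of meaningful size
(|r − 1| ≥ 0.05, i.e. ~10 % mosaicism — about the detection floor at 30×
coverage); ratios ≥ 1.4 / ≤ 0.6 are reported as full trisomy/monosomy.
GC correction, mappability masking and segmental mosaicism are out of
scope.

## Synthetic data

Every generator is a pure function of (specification, seed) and returns
its planted truth.  The depth pseudo-caller reports dosage events ≥ 5 kb
with uniform ±500 bp breakpoint jitter, including repeat-flanked events;
the pair pseudo-caller reports exact breakpoints with pair support
~ Binomial(depth, ½) but omits events whose breakpoints fall in
annotated repeats.  These blind spots are stylized from the qualitative
behaviour of read-depth vs discordant-pair callers (small events missed
by depth analysis; recurrent repeat-flanked events missed by pair
analysis) and are emulations, not calibrated models.  Probe series add
Gaussian noise (default σ = 0.15, a typical array noise level) around
the copy-number step function at 18-kb spacing.  SNV sites are
Poisson-placed with separate heterozygous (1/1500 bp) and homozygous
(1/2000 bp) densities — typical 30× WGS call densities — with the
heterozygous probability dropping to the error rate (0.001) inside
planted isodisomy.  Trio sites use biallelic markers at allele frequency
0.5.  STR reads are error-free and uniformly drawn over each haplotype
at depth/2, with guard bases ensuring flanks never extend the repeat
tract.  Depth bins are Poisson with mean `depth × bin_bp × dosage`.

What passing tests show — and do not show — about real data: the
generators contain no sequencing error (except SNV genotyping error), no
alignment ambiguity, no GC or mappability structure, and no caller
false positives, so recovery results here demonstrate correctness of the
algorithms under their stated models, not clinical sensitivity or
specificity.

## Problem sizes used in tests and the acceptance script

Chromosome-scale analyses use true GRCh37 chromosome lengths: mosaic
quantification simulates all 22 autosomes at 1-kb bins (≈ 2.9 M bins per
replicate, 10 replicates), and isodisomy recovery a 102-Mb
chromosome 15 (10 replicates).  Unit tests use scaled-down contigs where
the statistic is scale-free.  The full test suite runs in about two
minutes; the acceptance script in well under one.
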