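# Methods

`somavar` implements a comparative analysis of induced genomic variation in
plant genomes: copy-number structural variants (SVs) from tiling-array CGH,
single-base substitutions private to one individual of a jointly genotyped
cohort, T-DNA integration loci from paired-end resequencing, and exact
breakpoint structure (microhomology, filler) from junction sequences.  Each
stage has a synthetic-data generator that plants known events, so every
claim the test suite makes is a measured recovery against ground truth.

## CGH segmentation and SV calling

**Model.** A two-colour tiling-array hybridization of a test genotype
against its reference yields one log2 intensity ratio per probe, modelled
as Gaussian noise around 0 with a mean shift inside copy-number events
(negative for deletions, positive for duplications).  Probes are treated as
ordered points per chromosome; a segment's genomic span runs from its first
to its last probe position, so inter-probe gaps limit breakpoint resolution
to the probe spacing.

**Segmentation.** Each chromosome is segmented by recursive
permutation-accepted search.  At every step the best sub-window of the
current interval against its complement is found under the statistic

z(i, j) = |mean(x[i:j]) − mean(rest)| / sqrt(1/n_in + 1/n_out),

the two-sample mean difference normalized by its combinatorial scale.  The
window is accepted iff the raw mean difference is at least
`min_segment_difference = 0.1` log2 units **and** z exceeds the 0.99
quantile of the maximal z over 10 random shufflings of the interval's
values; the interval then splits at the window edges and recursion
continues.  Minimum segment length is 2 probes.  Two deliberate choices
here:

* *Why a window, not a binary split?*  A binary split dilutes a small
  mid-chromosome event over one side's mean, pushing the difference below
  both the 0.1 gate and the permutation null; testing the best window
  against its complement (the circular-segmentation form) detects such
  events while reducing exactly to the binary split when the best window is
  edge-anchored.
* *Why normalize?*  With the raw mean difference, the permutation null is
  dominated by tiny windows containing the event's own outlying values, so
  true splits essentially never exceed it.  The 1/n normalization makes
  windows of unequal size comparable; the published raw-difference
  threshold (0.1) still gates acceptance.

Ties in z are broken leftmost; a window and its complement (mathematically
equal z) are collapsed by rounding z to 9 decimals before comparison.  The
permutation stream is seeded per (sample, chromosome) from the run seed,
so segmentations are exactly reproducible.  Note that with only 10
permutations the acceptance threshold is essentially the permutation
maximum, so a null interval is falsely split with probability ≈ 1/11;
such splits are harmless for calling (see merging below) but mean raw
segment lists over-segment slightly.

**Calling.**  Segment means are thresholded at `upper = 0.3484` (copy
gain, "UpCNV") and `lower = −0.5257` (copy loss, "DownCNV"), strict
inequalities — a mean exactly at a threshold is not a call.  These
thresholds were calibrated empirically on hemizygous deletions and
duplications in characterized mutant plants; hemizygous and homozygous
deletions are deliberately not distinguished.  The production path
(`call_and_merge`) thresholds each segment's mean first, rejoins directly
adjacent same-class pieces (probe-weighted mean), and then applies the
3-probe minimum to the merged call, so the probe minimum is a property of
the event rather than of an arbitrary fragment.  A lone 2-probe segment is
dropped regardless of magnitude.  `candidate_review` reports segments that
fail the strict thresholds but pass thresholds relaxed by a factor in
(0, 1] — a mechanized stand-in for visual curation; it never creates calls.

**Heterogeneity filtering.**  Residual variation segregating within the
background cultivar masquerades as induced SV.  A call recurring with the
same class at the same location in ≥ 2 plants of one background group is
flagged (never deleted) and excluded from downstream counts.  Default mode
"exact" requires identical chromosome and start/end probe indices, which is
well-defined because all samples share one array design; a "reciprocal"
mode (pairwise reciprocal overlap ≥ threshold) is provided because real
replicate hybridizations rarely reproduce boundaries perfectly.  The
operation is idempotent.

**Gene accounting.**  Genes (GFF3 `gene` features, 1-based inclusive) count
as duplicated/deleted when overlapping an unflagged call by ≥ 1 bp, once
per sample per class.  Class summaries report total unique genes, per-
genotype max/median/min gene counts, the number of genic segments, and
mean/median segment size over genic segments only — absent, not zero, when
a class has no genic segment.

## Private homozygous substitutions

A de novo single-base mutation is expected homozygous in exactly one
individual.  From a jointly genotyped multi-sample VCF (biallelic SNVs
only; indels and multiallelics are counted and skipped), a site is kept iff

1. every sample has depth ≥ 5 reads (FORMAT/DP, falling back to the AD
   sum; absent depth fails the rule),
2. no sample is heterozygous or missing,
3. exactly one sample is homozygous-alternate and the others are
   homozygous-reference (sites monomorphic for either allele are excluded —
   neither can be private).

The depth rule is applied site-wide (any under-covered sample drops the
site), the conservative reading of a site-level filter; a carrier-only mode
is available behind `depth_scope="carrier"`.  Region exclusions (1-based
inclusive, optionally restricted to one sample) subtract stretches known to
be heterogeneous in a background cultivar rather than induced; the removal
count is reported.  Ti/Tv is transitions/transversions and is reported as
absent when there are no transversions.

## T-DNA insertion mapping

Reads are matched to the construct sequence between the left border (LB)
and right border (RB) only — vector backbone is out of scope.  The built-in
matcher uses exact 21-mer seeds with ungapped extension and requires ≥ 90%
identity over ≥ 90% of the read on either strand; a read with several
equally good placements gets mapq 0.  Externally produced SAM is ingested
equivalently (primary alignments, aligner mapq).  At fixture scale the
matcher is exact because simulated reads are error-free; on real data an
external aligner via the SAM path is the expected route.

"Orphans" are read ends whose mate matched the construct but which did not
themselves.  Orphans are placed on the host; those that fail full-length
placement (junction chimeras) are rescued by their longest exact host
prefix/suffix anchor (≥ 30 bp).  Forward-strand orphans pile up on the
upstream flank and reverse-strand orphans downstream; strand-specific
clusters (linkage gap 2× mean insert size) are paired across up to 20 kb to
tolerate insertion-adjacent deletions that push the flank pile-ups apart.
A call needs ≥ 3 supporting pairs per flank (configurable).  Orientation:
left-flank mates hitting the construct reverse strand mean LB faces the
left flank, i.e. the construct runs LB→RB on the host forward strand
("+"); the reported coordinate is the innermost host base adjacent to the
LB, per the locus-table convention.  Calls whose support derives > 50% from
construct elements with known genomic paralogs *and* whose coordinate falls
in a listed paralog region are flagged, not deleted.

**Junction refinement.**  Reads unplaced on both targets are tested for a
host prefix (or suffix) of ≥ 15 exact bases whose remainder touches the
construct; the modal end-of-prefix coordinate pins the insertion point
exactly, and the modal start-of-suffix coordinate pins the host resumption
point after any adjacent deletion.  The synthetic generator guards against
accidental one-base ambiguity at these junctions (reference continuation
equal to the first inserted base); a planted right-side homology with no
filler leaves the resumption genuinely ambiguous within the homology tract
and is documented as such.

**Adjacent deletions.**  With a located insertion, a window of ≥ 200 bp
near the call with depth < 0.2× the flank median is a deletion candidate;
within it the longest zero-depth run gives the bounds (a homozygous
deletion is strictly uncovered, and the zero run overshoots each true edge
by only ~read_length/coverage bases).  When no clean zero run exists
(hemizygous or noisy), the threshold-run edges are pulled back by their
expected overshoot, read_length × depth_ratio.  Host-host pairs whose
implied span exceeds mean + 3 sd and straddle the gap corroborate it (this
evidence cannot arise for construct-adjacent deletions, where the inserted
construct prevents host-host pairs from jumping the locus; it applies to
deletions without inserted sequence).  Junction-read bounds override depth
bounds exactly.  Flank coverage < 5× yields status "undetermined".

**Internal-element excision.**  Pairs with both ends construct-matched on
opposite sides of an annotated element whose outer span exceeds
mean + 3 sd while span − element length stays within mean + 3 sd are
counted as excision-supporting; an intact-only locus with a tight insert
distribution yields zero.

## Breakpoint junction resolution

A junction sequence (Sanger product or read consensus) is decomposed
against two anchored reference flanks by maximal exact prefix match (p, to
the left flank, which must extend past the breakpoint) and maximal exact
suffix match (s, to the right flank).  Matching is exact by design —
junctions come from consensus sequence and homology is treated as sequence
identity.  Flank matches under 15 bp give status "unresolved".

* **Overlap (p + s ≥ junction length):** the breakpoint is ambiguous
  within a single window of w = p + s − len bases; that window's sequence
  flanks both breakpoint ends (the classical microhomology-mediated
  end-joining signature), so it is reported as mh_left = mh_right = w,
  filler is empty, breakpoints are left-aligned, and the window is
  reported so either alignment convention can be reconstructed.
* **Gap (p + s < len):** the bases between the matched blocks are filler
  (they match neither flank continuation), the breakpoints are
  unambiguous, and the per-side homologies are measured independently:
  the left block's end against the reference immediately upstream of the
  right breakpoint, and the right block's start against the reference
  continuation past the left breakpoint (capped at k_max = 25 bp).

Deletion size is the count of reference bases absent between the retained
flanks (breakpoint_right − breakpoint_left − 1); zero is reported as
"no_event".  Duplication size is the duplicated span length.  The junction
generator plants both regimes by local edits on uniform random flanks with
explicit mismatch guards at every block boundary, which makes the planted
decomposition the unique maximal one; without filler a single shared tract
is planted, so it requires mh_left = mh_right.

## Synthetic data: what it does and does not emulate

The generators emulate: evenly spaced probes with Gaussian log2 noise and
planted mean shifts, events shared identically across samples (background
heterogeneity), cohort genotype matrices with private/shared/het/missing/
low-depth patterns and Poisson depths, and error-free 100 bp read pairs
with truncated-Gaussian insert sizes from homozygous (default) or 50:50
hemizygous alleles.  They do **not** emulate sequencing errors, base
qualities, PCR duplicates, GC or mappability bias, spatial array
artifacts, real repeat structure (host and construct are i.i.d. uniform
DNA), or reference bias.  Passing recovery tests therefore demonstrates
algorithmic correctness of the filters and estimators under their stated
models, not robustness to real-data artifacts; on real data, alignment and
genotype calling are delegated to external tools and ingested as SAM/VCF.

Generator conventions worth noting: cohort depths are Poisson around
`depth_mean`, clamped to ≥ 5 at planted private sites so planted truth is
recoverable; a `depth_mean` below 5 instead caps all depths at 4,
emulating a uniformly under-covered run in which every site fails the
depth rule.  Default fixture scales (60 kb host, 4 kb construct, 1 Mb
chromosomes at 2 kb probe spacing, 10–30× coverage, insert 350 ± 35 bp,
100 bp reads, 1.5 kb adjacent deletion, 6 bp filler, tens of private
substitutions per sample at ~20× depth) were chosen to mirror the
magnitudes of the study system while keeping a full recovery benchmark in
the order of seconds per stage.

## Parameters that matter

| Parameter | Default | Units | Role |
|---|---|---|---|
| `min_segment_difference` | 0.1 | log2 | raw gate for accepting a split |
| `min_probes_segment` | 2 | probes | smallest segment the search may create |
| `acceptance_percentile` | 0.99 | – | permutation quantile a split must beat |
| `n_permutations` | 10 | – | shufflings per acceptance test |
| `upper` / `lower` | 0.3484 / −0.5257 | log2 | UpCNV / DownCNV thresholds |
| `min_probes_call` | 3 | probes | minimum for a (merged) call |
| `min_recurrence` | 2 | samples | recurrence that defines heterogeneity |
| `min_depth` | 5 | reads | per-sample site depth for substitution calls |
| `max_alt_carriers` | 1 | samples | privacy rule |
| `k` | 21 | bp | seed length of the built-in matcher |
| `min_support` | 3 | pairs/flank | insertion-call support |
| `min_mapq` | 20 | – | orphan placements entering clustering |
| `depth_ratio` | 0.2 | – | deletion-candidate depth fraction |
| `k_max` | 25 | bp | microhomology search cap |

## Known limitations

* The segmentation acceptance threshold from 10 permutations is coarse
  (false-split rate ≈ 1/11 per interval); merging and the call thresholds
  absorb this, but raw segment boundaries over-segment in noise.
* Exact-mode heterogeneity matching assumes a shared array design; with
  noisy boundaries use reciprocal mode.
* The built-in matcher is ungapped and exact-seeded: indel-containing or
  high-error reads need the external-aligner SAM path.
* Insertion calls assume a single integration locus per cluster pair;
  tandem or multi-copy arrays are out of scope.
* Junction resolution is exact-match only; a polymorphism inside a flank
  block truncates the match and shifts the reported breakpoint.
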