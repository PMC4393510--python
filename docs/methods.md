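# Methods

This note documents the models, conventions and design choices behind
svsweep, and what the bundled simulator does and does not emulate.

## Fragment-size model and discordance

Each (sample, library) is modelled by the empirical distribution of the
*outer span* of properly oriented (+,−) same-chromosome pairs — the
distance from the leftmost mapped base of one end to the rightmost mapped
base of the other, always computed from mapped coordinates, never from the
alignment record's stored template-length field (which varies across
aligner dialects). The location/scale summary is the median and the
**unscaled** median absolute deviation: the discordance multiplier `k` is
quoted directly in MAD units (defaults 5 or 8), so no normal-consistency
factor (1.4826) is applied. For even-length inputs both statistics use the
lower-median convention, which keeps them integral and platform
deterministic; the cutoff `W = round(median + k·MAD)` rounds half-up.

A pair is discordant when interchromosomal, non-(+,−) after coordinate
ordering, or (+,−) with span > W. Undersized (+,−) pairs
(span < median − k·MAD) are *excluded* rather than clustered: they signal
insertions, which this caller does not model (the symmetric lower bound is
this package's choice; deletions, duplications, inversions and
translocations are the modelled classes). Spans used for profiling are
taken from the first N (default 10⁶) same-chromosome (+,−) pairs; the
discordant minority inflates neither median nor MAD materially because
both are 50th-percentile statistics.

Read-level filters (defaults: MAPQ ≥ 20, duplicates and
secondary/supplementary records dropped, both ends mapped) are stated
package defaults, not derived constants; all are configurable.

## Routing and sorting

Canonicalization orders the two ends by (header chromosome order, start);
all cohort headers must declare the same chromosome order or the run
aborts. Routing keys `(chrom1, chrom2, strand1, strand2)` give, per
chromosome pair, four orientation partitions that map to rearrangement
classes; partitions are processed independently (and may run
concurrently — outputs are defined to be identical under any scheduling,
which the implementation achieves by per-sample spill files concatenated
in sample-sheet order).

The external sort uses runs of at most `memory_records` records and a
k-way heap merge. The sort key is the full tuple
`(start1, end1, chrom2, start2, sample_id, read_id)` rather than the
leftmost coordinate alone: a total order makes the merged stream — and
therefore every downstream artifact — byte-reproducible regardless of the
memory budget. Runs and spills share one versioned TSV dialect so any
stage can be inspected or replayed in isolation.

## Sweep clustering

A pair mapped `[s, e)` on '+' places its breakpoint in `[e, s + W)`; on
'−', in `[e − W, s)`, with `W` the pair's *own* library cutoff. The
product of the two per-end intervals is the pair's breakpoint rectangle.
Two pairs support the same variant when their rectangles intersect on both
sides. This per-end interval screen is a deliberate relaxation of the
joint 2-D fragment-length constraint (gap₁ + gap₂ ≤ W): it is a
conservative superset, simpler to reason about, and per-library widths are
what make cross-library corroboration work.

The sweep maintains open clusters; for each incoming pair (sorted by
start1) it first closes clusters whose side-1 footprint lies entirely left
of the pair's side-1 interval (they can never gain members), then adds the
pair to the compatible cluster maximizing the worst-side overlap with the
cluster's running intersections, breaking ties toward the oldest cluster —
a deterministic rule that is provably equivalent to maximal
compatible-set enumeration when clusters are separated by more than twice
the largest cutoff (asserted against a clique-enumeration oracle in the
tests). The sortedness check is on start1, the invariant the sorted stream
actually guarantees (rectangle lower bounds are not monotone across
libraries on '−' strands).

Clusters reaching `cluster_cap` members mark loci of aberrant read depth
(typically collapsed reference sequence). They are dropped entirely —
truncated calls at such loci would be exactly the false positives the cap
exists to avoid — but remain in the sweep, absorbing further compatible
pairs, so a saturated locus cannot shed a stream of fresh sub-cap
clusters. The default cap is `max(100, round(10 × Σ mean depth))` over the
sample sheet. Dropped clusters are logged with their member counts;
member conservation (emitted + dropped = extracted discordant pairs) is a
tested invariant.

## Cohort analytics

Presence of a breakpoint in a sample means ≥ `min_pairs` (default 1)
supporting pairs from that sample. Labels are non-exclusive sets:
*germline* = present in ≥1 normal; *private* = present in exactly one
sample; tumor-/normal-private accordingly. A normal-private breakpoint is
therefore also germline — retaining that overlap is what makes germline
and tumor-private counts partition a fully classified call set. The
somatic FDR estimator, `100 · #normal_private / #tumor_private`, assumes
normal-private variants are false and that false somatic calls arise at
comparable absolute rates in tumor and normal data; loss of
heterozygosity in tumors makes it a mild overestimate on real cohorts.

`fdr_vs_n` draws, per focal pair and replicate, N additional pairs
uniformly without replacement from the remaining pairs; a candidate
(present in the focal normal, absent from the focal tumor) is a false
somatic call only if also absent from all 2N screening samples, with the
tumor-side analogue as denominator. At N = 0 it reduces exactly to the
pairwise estimator; the curve is non-increasing in expectation because
screening can only remove candidates.

Sample clustering restricts the matrix to germline deletion/duplication
calls with implied span `start2 − end1 ≤ 1 Mb` (the defensible reading of
a size cap for copy-number events), computes column-wise Jaccard
distances (empty unions get distance 1, with a warning) and
average-linkage agglomeration, serialized as Newick.

## Truth-set evaluation

Calls and truth deletions are reduced to 200 bp probes centered on the
breakpoint-interval midpoints (clipped at zero) — symmetric and
parameter-free. A call is a true positive iff both probes intersect both
probes of one truth deletion; TP counts distinct truth deletions detected,
so redundant calls do not inflate sensitivity. Entries whose probes touch
a read-depth exclusion region (any BED) are removed from both sets before
counting. TP and FP are exactly non-increasing in the support threshold.

## The simulator

Alignments are simulated directly in reference coordinates — no sequence,
no aligner. Each sample haplotype's donor genome is an ordered list of
reference segments (deletion removes, tandem duplication repeats,
inversion flips, balanced translocation exchanges arms); fragments are
sampled uniformly along the donor with lengths
Normal(median, 1.4826·MAD) truncated (clipped) at 2·read length, and each
read end is mapped back through the segment map. This yields the correct
class signature for junction-spanning fragments by construction, zero
coverage inside homozygous deletions, and realized span MADs matching the
configured MADs (the 1.4826 factor converts the configured MAD to the
Normal σ). Reads that would cross a junction (split reads) are dropped
whole-fragment; the caller consumes only cleanly mapped ends.

Germline SVs are genotyped per *individual* — a tumor and its matched
normal share the genotype — at a configurable carrier frequency;
heterozygous carriers route each fragment to a haplotype with probability
1/2; somatic SVs are het in a single tumor. `presence_from_genotypes`
converts the genotype table to a presence matrix with a per-entry
detection-dropout probability, modelling the finite sensitivity that
creates false somatic candidates in matched designs; cohort-level
analytics can thus be exercised at realistic cohort sizes without
read-level simulation of dozens of genomes.

Not emulated: base-level errors, mappability artifacts, chimeric
molecules, real insert-size skew (distributions are symmetric), and
reference bias. Passing tests therefore demonstrate algorithmic
correctness on the stated signal model, not robustness to alignment
artifacts in real data.

## Problem sizes used in the tests

The deletion-recovery study condition uses one sample with three
libraries (medians 300/400/500 bp, MADs 15/30/50) at 10× each (30×
aggregate), 50 homozygous deletions of 1–50 kb planted on a 6 Mb
chromosome with no noise pairs. The cohort analytics condition uses 20
tumor-normal pairs, 250 germline-or-somatic CNVs (carrier frequency 0.35,
25% somatic) with 12% detection dropout. The joint-vs-single comparison
uses ten 5× carriers of 20 deletions on 1.2 Mb. Oracle comparisons use
200 random partitions of ≤ 50 pairs; sort determinism uses 10⁴ records
under budgets {1, 7, 10⁶}.

## Known limitations

* Insertions (undersized pairs) and read-depth CNV signals are out of
  scope; split-read refinement is not attempted, so breakpoint intervals
  retain library-scale width.
* The greedy assignment is order-dependent for clusters closer than the
  separation bound; the tie-break makes it deterministic but not globally
  optimal.
* The somatic FDR estimator inherits its stated assumptions; cohorts with
  pervasive tumor LOH or very uneven normal coverage violate them.
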