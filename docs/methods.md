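# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open (BED convention); the
GTF/GFF3 reader converts from 1-based closed at the I/O boundary, so GTF and
BED12 encodings of the same gene produce identical internal models. All
"upstream"/"downstream" semantics are transcript-oriented: minus-strand
depth arrays are reversed before analysis, and spliced 3'UTR offsets count
from the CDS–3'UTR junction toward the 3' end. The junction itself is a
half-open boundary; the junction base belongs to the 3'UTR side. This fixes
an otherwise arbitrary tie: a fragment whose interval ends exactly at the
junction has touched only the CDS and is never called junction-spanning.

Multi-transcript genes are collapsed by default with `transcript_policy=
"union"`: the union of CDS exonic intervals and the union of 3'UTR intervals
across transcripts, with bases claimed by both unions assigned to the CDS.
This mirrors what region-BED coverage counting measures when one BED line
per region is used. A `longest_transcript` policy is available where a
single representative isoform is preferred.

## Expression, effective length, and the expressed filter

Per-region expression is reads per effective-kilobase per million mapped
reads, where the effective length is the count of bases with non-zero
coverage rather than the annotated length. Zero assigned reads give
expression 0 regardless of effective length; a positive count over zero
covered bases is rejected as an impossible state. Reads are counted once per
region they overlap by ≥ 1 aligned base (CIGAR-aware), so a read straddling
the junction contributes to both regions' counts — consistent with
independent per-region overlap counting — but is subtracted once from the
gene-level total used by the ≥ 5-read expressed filter, so it cannot be
double-counted there. The filter is applied per gene (configurable to per
region). BAM ingestion keeps primary alignments with MAPQ ≥ 20 by default;
bedGraph ingestion requires a companion per-region read-count table, since
depth alone cannot recover read counts.

## The fractional ratio and Hi/Lo classification

The ratio `r = utr / (utr + cds)` is computed on normalized expression
values: within one replicate the library size cancels, and effective-length
normalization makes regions of very different lengths comparable. A
`ratio_basis="mean-depth"` option computes the ratio on mean per-base depth
instead. When both expressions are zero the ratio is undefined and the
record is flagged rather than forced to a number. Classification uses strict
inequalities — `r > 0.6` Hi 3'UTR, `r < 0.4` Hi CDS, values exactly at a
threshold intermediate — and non-expressed genes are excluded before any
threshold is applied. Replicate concordance of the Hi set is Jaccard × 100
by default; because "percent identity" between call sets is a convention
rather than a formula, overlap-over-smaller is implemented as an
alternative and the metric used is recorded in the output.

Multi-replicate runs report per-replicate records plus a pooled record
(summed counts, depth-pooled effective lengths, summed library sizes); the
pooled record is what the exported class lists rank.

## Consensus peaks, valleys, and pattern types

Per-base FPKM treats each base as a 1-bp feature: `fpkm = depth × 10⁹ /
library`. This is the only length-consistent reading of FPKM at single-base
resolution, and it makes peak calls invariant to scaling depth and library
size together; the threshold is configurable so any alternative convention
can be matched by rescaling.

The default consensus intersects bases first: a base is "above" when its
FPKM strictly exceeds 100 in at least `min_replicates` replicates (default:
all supplied), and peaks are maximal above-runs strictly longer than 150 bp.
The alternative (`per_replicate_intersection`) calls length-filtered peaks
per replicate and intersects the intervals; both are exposed because the
per-base reading is the more literal one but the two genuinely differ when
replicate runs overlap by less than the minimum length. Valleys use the
complementary non-strict inequality (≤ threshold) so that every base decided
in all replicates belongs to at most one of the two sets, and are restricted
to the annotated 3'UTR.

Pattern rules are applied in order and the first match wins, with the full
rule trace reported per gene:

* **type i** — ≥ 2 peaks inside the 3'UTR with ≥ 1 valley between a
  consecutive pair;
* **type ii** — a single peak abutting the junction (or within 50 bp of it
  with CDS signal reaching the junction) into a 3'UTR ≤ 1000 bp;
* **type iii** — 3'UTR ≥ 2000 bp with a peak, and all above-threshold CDS
  runs confined to a terminal stretch ≤ 25% of the CDS adjacent to the
  junction (at least one such run is required: the pattern describes a short
  *leading* CDS stretch, not an entirely silent CDS).

The short/long UTR cutoffs (1000/2000 bp) and the 50-bp junction slack are
package defaults for thresholds the pattern descriptions leave qualitative;
all are configurable. A long-UTR gene with several peaks and a confined CDS
matches type i first by construction.

## EST and element alignment

Fragments are classified by ≥ `min_overlap_bp` (default 1) overlap with the
CDS and 3'UTR interval sets; the partition UTR-only / CDS-only / mixed /
outside is exhaustive and exclusive. The junction profile reports, for
signed 250-bp bins around the junction (clipped to the gene span and flagged
partial), the fraction of counted ESTs overlapping each bin. An EST "spans"
an internal valley when its genomic extent covers the valley's full span;
only valleys flanked by peaks on both sides count as internal.

Elements are assigned to peak / valley / elsewhere by midpoint (any-overlap
assignment would double-count long elements lying across a peak edge). The
permutation test places each element uniformly at random, length-preserving,
within the gene span and uses the fraction of midpoints inside peaks as the
statistic, with the add-one estimator `p = (1 + #{null ≥ obs}) / (1 +
n_perm)`: p is never zero, deterministic given a seed, and degenerates to 1
with a warning when peaks cover the whole span.

## The synthetic-data generator

The generator emulates exactly what the analysis consumes: per-base coverage
over genes with designed peak/valley architecture, replicate count noise,
library-size differences, EST sets with a designed class mixture, and
element tracks placed into designed peaks or valleys. It does **not**
emulate read-level artifacts — mappability gaps, 3' bias, duplicated
fragments, spliced-alignment errors, multi-mapping — so passing the closed
loop demonstrates the correctness of the statistics and calling rules, not
robustness to alignment pathology in real data.

Designed FPKM converts to expected depth by inverting the per-base FPKM
convention (`depth = fpkm × library / 10⁹`). The default library size is
5×10⁸ mapped reads per replicate, deep pooled-replicate scale: it places the
FPKM = 100 decision boundary at depth 50, where Poisson fluctuation cannot
fragment a > 150-bp run designed at twice the threshold, so designed peak
boundaries are recoverable essentially exactly. Per-replicate library sizes
get a uniform ±20% jitter, and expected depth scales with the realized
library so designed FPKM is library-invariant, as normalized coverage is.
Noise is Poisson per base by default; a Gamma–Poisson alternative applies
one multiplicative factor per 50-bp tile for overdispersion stress tests.
Region read counts are derived as aligned bases divided by the 100-bp read
length. Every design records its exact expected ("true") ratio computed
from the realized profiles — the CDS background is solved from the target
ratio and clamped below at 5 FPKM so no designed region loses coverage,
which can pull an extreme target ratio slightly inward; the truth table
always stores the realized value.

The default scenario ships 30 genes across one synthetic chromosome, 4
replicates: 8 type-i, 8 type-ii and 6 type-iii genes, 4 expressed genes with
uniform sub-threshold 3'UTRs, 2 mid-length single-internal-peak genes that
match no pattern rule, and 2 silent genes below the expressed filter, with
designed ratios spanning 0.05–0.95 and peak FPKMs at ≥ 2× the calling
threshold. EST mixtures default to 0.85/0.05/0.10
(UTR-only/CDS-only/junction-spanning) at n = 200 per gene; miRNA-site
elements are placed inside designed peaks and CpG/TF/H3K27ac/DNase elements
inside designed valleys where a window fits.

Identical seeds reproduce every output file byte-for-byte.

## Numerical and testing choices

Strict inequalities are used everywhere the defining phrases are strict
(> 150 bp, FPKM > 100, ratio > 0.6 / < 0.4); boundary values are tested
explicitly. The consensus peak caller is checked for exact equality against
an independent boolean-matrix run-length oracle on 1000 randomized
piecewise-constant profiles (up to 10 kb × 6 replicates) whose values
deliberately straddle the threshold. Closed-loop tests require designed
Hi/Lo labels back for every gene with true ratio outside [0.35, 0.65],
designed peak counts exactly with boundaries within ±25 bp, designed pattern
types, and EST class fractions inside per-gene 95% binomial intervals at the
expected coverage rate (a fixed fraction of 95% intervals missing is the
correct behavior of a calibrated generator, so the test checks coverage and
a pooled goodness-of-fit rather than demanding every interval contain its
draw). Permutation p-values are verified super-uniform under a uniform
placement null across 2000 seeded trials. Simulation sizes (30 genes, ≤ 5 kb
UTRs, 4 replicates) keep the whole suite and the closed loop fast while
exercising every rule branch.

## Known limitations

* BED12 export encodes the CDS as the thick region, which cannot represent
  a CDS interleaved with 3'UTR exons; such structures round-trip through
  GTF only.
* Junction-straddler subtraction in the expressed filter requires BAM input
  (read identity); bedGraph + count-table inputs treat per-region counts as
  disjoint.
* EST-to-gene assignment follows the supplied BED naming (gene|label) or
  falls back to gene-span overlap; ambiguous multi-gene fragments are
  counted for every overlapped gene.
* The pattern rules are deterministic thresholds, not a statistical model;
  genes near the short/long UTR cutoffs change type with the cutoffs, which
  is why the rule trace is part of the output.
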