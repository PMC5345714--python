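# Methods

## Model

`synmap` treats comparative mapping as an order-consistency problem
between two coordinate systems: a genetic map (markers ordered in cM per
linkage group, LG) and a physical genome (chromosomes with bp
coordinates). Homology anchors tie the two together; shared-synteny blocks
are the maximal stretches where the two orders agree, and those blocks are
the only evidence used to transfer positions of unmapped sequences onto
the map. No alignment scoring, gap model, or paralogy handling is
involved: the unit of evidence is the anchor, and the only relation tested
is relative order.

### Anchors

Hits are read from the common 12-column tabular search format; only the
subject fields are interpreted. A hit is significant when its e-value is
strictly below the threshold (default 1e-10). Per query and comparison
species:

* significant hits on ≥ 2 chromosomes → the query is discarded
  ("multi-chromosome"); multi-copy sequences cannot anchor a unique
  position;
* otherwise the best hit — highest bitscore, ties broken by lower
  e-value, chromosome id, lower coordinate — defines the anchor, at the
  *smaller* of its two subject coordinates, so minus-strand hits (printed
  with start > end) get a well-defined position. Strand is not used
  downstream. Multiple hits on one chromosome are legal (tandem
  near-duplicates, split alignments); collapsing them by best score is
  this package's documented choice.

### Collinearity with tolerance

Within one (species, LG), anchors are ordered by (cm, bp, locus_id). A
candidate run is *feasible* under orientation s ∈ {+1, −1} iff every pair
of anchors with distinct cM whose bp order contradicts s satisfies

    |Δcm| < τ·(LG length)  and  |Δbp| < τ·(chromosome length),

with τ = 0.025 by default. Design notes:

* **All pairs, not only adjacent ones.** A reversed segment with small
  internal marker gaps looks locally innocuous pair-by-pair; only the
  pair spanning the segment reveals the rearrangement. Checking all pairs
  makes block splitting depend on the *displacement* of a departure
  rather than on marker spacing, which is what an order-tolerance of
  "2.5 % of the axis" is meant to capture.
* **Conjunctive on the two axes.** A departure must be small on the map
  *and* the genome to be forgiven. Forgiving on either axis alone would
  wave megabase-scale inversions through wherever cM resolution is
  coarse (zero-recombination regions) and vice versa.
* **cM ties are never violations.** Zero-recombination bins are pervasive
  in dense maps (co-segregating loci are placed at the representative's
  position); the map genuinely does not order such loci, so any genome
  order within a bin is consistent. Within a bin, anchors are taken in bp
  order.
* A LG length of 0 (single-locus or fully tied group) disables tolerance
  on the map axis; nothing is forgiven there.

### Segmentation

Run feasibility is hereditary on contiguous subruns, so each start index
has a single maximal reach; the per-LG sequence is partitioned by exact
dynamic programming minimising (number of runs, anchors left in singleton
runs), reconstructed leftmost-longest. An exhaustive-enumeration oracle
(`oracle_segment`, ≤ 12 anchors) implements the same objective
independently and pins the detector's behaviour in tests (1000 random
instances). A greedy left-to-right sweep would find the same minimal run
count — hereditary feasibility guarantees it — but can disagree with the
enumeration objective on tie-breaks, which is why the DP formulation was
chosen.

Runs of a single anchor are not blocks ("at least two loci") but are
counted as unblocked anchors in the validation report. Block orientation
is the sign of the Spearman rank correlation between cM and bp (0 when
all cM or all bp are tied). Anchors on a different chromosome interrupt a
run; loci with no significant hit do not — they carry no positional
evidence in that genome.

### Placement

A transcript anchor is placed through every block of its species whose
genome span contains its bp and which holds ≥ 3 mapped loci ("more than
two"): with only two loci the transcript's interval would be the whole
block, adding no information beyond block membership. The bracketing
adjacent anchor pair on the bp axis defines the cM interval (provably the
smallest the block supports); exact bp coincidence with an anchor yields a
zero-width interval flagged `zero-width`. Overlapping blocks (different
LGs tiling one chromosome) each produce a placement; reconciliation marks
cross-LG disagreement as `conflict` and intersects intervals otherwise,
flagging empty intersections `inconsistent-interval` with the union kept
for inspection. No point estimate is interpolated inside the interval:
the method's resolution is the flanking-marker interval, and pretending
otherwise would overstate it.

## Simulator

The generator emulates the data a comparative-mapping study consumes, not
the sequencing that produced it (no reads, no alignments):

* **Map**: per LG, marker bp positions are uniform on an ancestral
  chromosome; cM is a monotone piecewise-linear transform of bp (5
  recombination-rate windows, rates uniform in [0.5, 1.5]× the mean),
  normalised to the configured LG length; a configurable fraction of loci
  (default 0.30) is collapsed into zero-recombination bins.
* **Comparison genomes**: each species applies planted inversions
  (mirror a contiguous anchor run inside its bp span) and translocations
  (move a run to a uniformly chosen other chromosome), then
  truncated-Gaussian bp jitter (default sd 10 kb, cap 30 kb on 24 Mb
  chromosomes) emulating assembly error. Map-axis noise comes from ties
  and rate variation only — jitter is deliberately bp-only.
* **Decoys** (defaults): 35 % of loci have no significant hit in a given
  species, 3 % hit two chromosomes, 3 % have only sub-threshold e-values,
  10 % carry a worse-scoring secondary same-chromosome hit; so every
  filter path is exercised on every run.
* **Transcripts** are planted between two ancestrally adjacent anchors of
  a truth block (placeable), inside 2-anchor blocks (too small), in
  anchor-free chromosome tails (outside all blocks), or as
  multi-chromosome / weak-e-value decoys. A planted transcript's true map
  position is the midpoint of its bracketing pair's cM values, which any
  correct placement interval must contain.

### Ground-truth conventions

Truth blocks follow the planted rearrangement boundaries with two
conventions that mirror what any order-based detector must do at a
breakpoint:

* the leading anchors of an inverted run whose mirrored positions still
  continue the preceding run within tolerance (prefix span < τ on both
  axes) belong to the preceding block — the mirrored first anchor always
  does, since it extends the ascending run with no violation at all;
* a trailing remainder whose span is below tolerance on both axes merges
  into the following block.

These margins are genuinely ambiguous — the data cannot distinguish the
two readings — so truth adopts the deterministic convention and
transcripts are never planted across such margins. Rearrangements are
planted only in tie-free cM stretches (a breakpoint inside a
zero-recombination bin is unresolvable on the map axis) and must span at
least `min_rearrangement_span_frac` (default 0.05, i.e. 2× τ) of one
axis, so every planted rearrangement is detectable in principle. Sites
are drawn uniformly from the exhaustively enumerated feasible set; an
empty set raises an infeasible-config error rather than silently planting
fewer rearrangements.

`recovery_metrics` scores exact anchor-set recovery of truth blocks
(precision/recall), the fraction of placeable transcripts whose placement
interval contains their true position (recall), and the fraction of
outside-planted transcripts placed anyway (false-placement rate).

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| τ (`ToleranceRule.tau`) | 0.025 | order-departure tolerance, fraction of each axis |
| e-value threshold | 1e-10 | strict upper bound for a significant hit |
| min block loci | 2 | a block needs at least two anchors |
| min placement loci | 3 | a block must exceed two loci to place transcripts |
| `SimConfig` scale | 24 LGs × 95 loci, 87.72 cM, 24 Mb | consensus-map-scale defaults |
| jitter sd / cap | 10 kb / 30 kb | assembly-error emulation, well below τ·chromosome |

Raising τ merges blocks monotonically (verified property); lowering the
e-value threshold trades anchors for specificity upstream of everything
else.

## Numerical choices

* cM values are stored at full precision; statistics are rounded only at
  presentation (2–3 decimals). The mean marker interval is total map
  length over within-group adjacencies, n_loci − n_groups, and is
  reported as undefined when every group has one locus.
* Group length is the maximum cM position (maps start at 0); a
  single-locus group has length 0. Negative cM is rejected, not shifted.
* Deterministic tie-breaks everywhere: anchors sort by (cm, bp,
  locus_id); best hits by (−bitscore, evalue, chromosome, bp); all
  exports use stable sort keys, so identical inputs give byte-identical
  outputs.
* BED export is 0-based half-open; block spans elsewhere are 1-based
  inclusive extrema of member anchors. Block sizes are span extrema
  differences; all-tied-cM blocks contribute 0 cM to map totals.
  Overlapping blocks are summed unmerged in genome-proportion summaries
  (a warning fires if summed spans exceed the genome).

## What passing tests show — and what they do not

The simulator produces exactly the structure the detector models:
piecewise-stationary marker density, clean rearrangements of whole anchor
runs, independent bp jitter, e-values drawn below or above threshold by
construction. Perfect recovery on it demonstrates internal correctness —
the tolerance rule forgives what it claims to forgive and splits what it
claims to split — not field performance. Real data add paralogy beyond
the multi-chromosome filter, assembly gaps and misjoins that are not
mean-zero jitter, map-order errors from genotyping, and genuinely shared
ancestral rearrangement structure between comparison species; block
counts and placement rates there depend on divergence and assembly
quality, as the wide per-species ranges in published comparative studies
show.

Problem sizes in the test suite and acceptance script (3–8 LGs, 14–40
loci per LG, 2 species, 50-seed noise-free sweeps, 1000-instance oracle
sweeps) are the package's chosen verification scale; the detector itself
runs comfortably at consensus-map scale (24 × 95 anchors per species in
well under a second).

## Known limitations

* Blocks never span chromosomes, and double-conserved synteny (one map
  region matching two chromosomes after whole-genome duplication) is
  deliberately out of scope — such queries are discarded by the
  multi-chromosome rule.
* Tolerance is pairwise-conjunctive but applied per discordant pair;
  many independent sub-threshold departures in one run are all forgiven,
  which is intended (noise), but adversarial chains of them could hide a
  staircase rearrangement below τ per step.
* Reversal symmetry (mirroring a chromosome negates orientations and
  preserves blocks) is exact on tie-free data; when a block boundary
  falls inside a zero-recombination bin, which tied member joins which
  flanking block follows the bp sort and is coordinate-convention
  dependent.
* Placement transfers order, not distance: the cM interval is bounded by
  flanking markers, and nothing is claimed about where in the interval
  the transcript lies.
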