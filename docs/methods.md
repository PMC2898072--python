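# Methods

This note documents the models, numerical conventions and deliberate
design choices behind `adnapipe`, and what the synthetic-data tests do
and do not demonstrate about real ancient-DNA data.

## Synthetic genome pair

Two genomes descend from a random uniform-composition ancestor by a
time-symmetric two-lineage simulation: each lineage receives
substitutions at `pair_divergence / 2` and indel events at
`indel_rate / 2` per site, so that an outgroup attaching anywhere along
the inter-genome path sees a roughly central ancestor — the geometry the
triangulation estimator assumes.  Default calibration: pairwise
substitution rate **0.012/site** and indel rate **5×10⁻⁴ events/site**,
emulating a human/chimpanzee-like pair at a 6.5-Myr split.

Choices where the design was open:

* **Substitution spectrum**: replacement bases are uniform over the
  three alternatives (no transition bias).  This is the simplest neutral
  model; real primate genomes have a ~2:1 transition excess, so the
  synthetic pair carries *more* informative transversions per aligned
  site than real data would.  Transversion-only estimates here are
  correspondingly less noisy than a real run of the same size.
* **Indels**: lengths geometric (parameter 0.5, mean 2 bp), insertions
  uniform over ACGT; sites deleted on both lineages leave no alignment
  column (no gap/gap columns, by construction and by invariant).
* **Coordinates**: 0-based half-open everywhere; minus-strand features
  are stored on forward coordinates with a strand flag.
* The substitution matrix estimated from an alignment uses a +1
  pseudocount per off-diagonal cell and tallies mismatches in both
  directions, making it symmetric and strictly positive at any size.

The alignment object is the exact record of the applied mutations, so it
doubles as ground-truth orthology: liftover is per-column image
enumeration, not an approximation.  What the synthetic pair does *not*
contain is paralogy — real genomes produce ~0.2–0.3% misplaced reads
through segmental duplications and repeats, which here exist only when
a test plants them explicitly.  Clean-pair results therefore bound the
alignment machinery's intrinsic bias, not the paralogy-induced one.

## Fragment simulator

Fragments are sampled uniformly from genome A with lengths from a
discretized lognormal (σ = 0.35, support 20–200 bp, re-centred to a mean
of **63 bp**, the typical mean length of the fragmented molecules this
models); strands are uniform.  A candidate is kept only if lifting its
interval to genome B and back recovers it exactly, mirroring the
round-trip pre-filter a real pipeline applies through whole-genome
alignments.  Four steps then transform each fragment (divergence X in
Myr, total tree length D = 13 Myr):

1. at every aligned mismatch column, switch to the genome-B variant with
   probability X/D;
2. mutate every site with probability X/D × r (r = the pair's average
   substitution rate), replacement drawn from the estimated matrix;
3. apply every overlapping indel event of the pair alignment with
   probability X/D, as a unit, clipped to the fragment;
4. flip minus-strand fragments to read orientation, then add
   deamination damage.

Step order is fixed 1→2→3→4; step 2 may hit a site already changed by
step 1 (nothing forbids it).  All changes are logged; `replay_truth`
rebuilds every read byte-exactly from the genome, and the test suite
asserts this over damaged, indel-carrying, minus-strand reads.

### Damage model

Overhang lengths at both ends are independent draws from the geometric
law **P(L = k) = (1 − p) pᵏ, k ≥ 0, p = 0.3**, so P(L ≥ 1) = 0.3; if the
two draws overlap, the longer one is truncated.  Within the 5′
single-stranded overhang each C deaminates (C→T) with probability
**0.845**.  For the 3′ overhang, with probability **0.8** (the nick
probability) the reported strand shows the complementary strand's
filled-in copy, so deamination appears as G→A; otherwise as C→T.  In
the double-stranded interior each C (and, symmetrically, each G for the
complementary strand) deaminates with probability **0.015**.  This
yields the canonical pattern: C→T clustered at 5′ ends, G→A at 3′ ends,
a low uniform interior rate, and — crucially — *only transitions*, so
transversion-restricted analyses are exactly damage-free.

Closed forms used by the tests: the 5′-terminal C→T rate is
q·0.845 + (1 − q)·0.015 with q = 0.3, and the per-position rate decays
geometrically toward 0.015 with distance from the end.

## Local search

A Mega-BLAST-like seeded search: contiguous **16-mer** exact seeds
(packed 2-bit integers in a sorted array; reverse-strand hits via the
reverse-complemented query), ungapped two-directional X-drop extension
(budget 20 raw-score units), then gapped affine X-drop extensions
(budget 30) forward and backward from the midpoint of the ungapped core.
Scoring: match +1, mismatch −3, gap open −5, gap extend −2 (a gap of k
columns costs 5 + 2k).  Bitscores use the Karlin–Altschul transformation
with λ = 1.374, K = 0.711 (the standard ungapped values for +1/−3,
a good approximation under these stringent gap costs); e-values use
query length × total database length with no edge correction.  At most
ten hits per database pass the e < 0.001 cutoff, ranked by bitscore,
then raw score, then leftmost target coordinate.

The heuristic's score is never above the exhaustive Smith–Waterman
optimum and equals it on indel-free instances (asserted against an
independent full-DP oracle); its sensitivity losses — no seed, early
truncation — are intentional, since quantifying them is the point.

Classification: a read is endogenous iff its best overall bitscore is to
a target genome; a tie with a contaminant database is conservatively
called contaminant; equal-bitscore hits within the winning genome clear
the unique-best flag.

## Alignment algorithms

* **Semi-global**: global in the read, free end gaps on the genomic
  window only; the window is the local-hit interval padded by one read
  length on each side, which guarantees any positively scoring placement
  fits inside.  The strictly-positive score filter drops reads whose
  unaligned remainder is more dissimilar than chance.
* **Three-way (3DP)**: optimal sum-of-pairs alignment over the 3D
  lattice.  A column is scored as the sum of its three pairwise
  projections; gap-vs-gap in a pair scores 0; affine gaps are handled by
  keeping the previous column's per-sequence advance mask (3 bits) in
  the DP state — a gap column is charged open+extend when that sequence
  advanced in the previous column, extend otherwise.  Traceback prefers
  all-advance columns, then a gap in the ancient, closer, farther
  sequence, in that order (determinism).
* **Dijkstra variant**: the same lattice traversed best-first after
  converting maximization to minimization with the per-column cost
  `match × (#sequences advanced) − column score`, which is ≥ 0 for every
  column type, so the first settled final node is optimal and scores
  equal the exhaustive DP *exactly* (property-tested on random triples,
  including dissimilar ones).  For ~1%-divergent 63-bp triples the
  traversal settles a thin diagonal tube instead of the full lattice;
  workspace buffers are reused across calls and only touched entries
  are reset.

All DP kernels are integer-scored numba routines.

## Filters and triangulation

Filter boundaries: reciprocal liftover overlap ≥ 0.90 passes (per
direction, denominator = the destination hit interval); bitscore gap
≥ 6 bits passes; read length must strictly exceed 35 bp.  The filters
are a pure conjunction — the reporting order (unique → orthology →
bitscore → length → positive score) is presentational only.

Lineage assignment ignores columns containing any gap (conservative)
and all-different columns (not assignable with one change).  The
transversion tallies are computed *transition-blind*: bases collapse to
their purine/pyrimidine class before comparison.  For ordinary Hs/Cs
columns this coincides with asking whether the changed pair is a
transversion; its advantage is exactness — C→T/G→A damage never changes
a base's class, so damage provably cannot move a transversion-only
tally, even by creating all-different columns.

The estimate is Hs/(Hs + Cs) × D and always lies in [0, D].  Confidence
intervals are a percentile bootstrap over fragments (B = 2000, α = 0.05
by default; degenerate replicates with an empty denominator are skipped
and counted).  The bootstrap is this package's choice of interval
method; no multiple-hit correction is applied anywhere, deliberately.

## 454 preprocessing conventions

A flow value is *positive* when it calls at least one base (≥ 0.5);
two flows *agree* within τ = 0.49 (same homopolymer call).  Synthesized
flowgram noise is Gaussian truncated to ±0.49, so rounding always
recovers the called sequence.  Adapter trimming scores each candidate
trim point — flows whose cycle position matches the adapter's first
base — by +1 per agreeing flow and −|Δ| per disagreement, normalized by
overlap, and takes the 5′-most positive point; anchoring on the first
base's flow prevents insert signal from being compared against the
adapter's leading empty flows.  Duplicate clustering buckets reads by
the indices and rounded values of their first six positive flows, links
two reads when the shorter aligns to the longer (free end gaps on the
longer, affine costs) at ≥ 89% identity over the shorter's full length,
and takes connected components, making the result independent of input
order.

## Problem sizes and statistical resolution

The shipped experiments run at desk scale: genome pairs of 1 Mb,
20,000 fragments for the 1-Myr recovery experiment (three seeds) and
10,000 per divergence point for the 1–6-Myr ladder.  At that scale one
seed yields ≈ 9,000 informative transversion sites, so the
transversion-only estimate at X = 1 Myr carries a binomial sampling SD
of about 13·√(p(1−p)/9000) ≈ 0.037 Myr (3.7% relative; expected
absolute deviation ≈ 2.9%).  Observed estimates are unbiased within
those bounds.  Statements of sub-percent estimator accuracy require a
read count several times larger (the regime of the full-scale study the
simulator emulates); at the shipped sizes the meaningful checks are
unbiasedness, CI coverage, the direction of the damage-coincidence bias
(raw transition-inclusive estimates overestimate small divergences),
and its elimination by the transversion restriction plus filters.

## Known limitations

* No sequencing-error model beyond deamination; no quality scores; no
  binary SFF input (flowgrams are synthesized or read from TSV).
* Single colinear alignment block per genome pair; no rearrangements,
  no repeat/paralog background (planted duplications only), no GC
  isochores.
* The Dijkstra traversal is exact but assumes the default scoring
  scheme's structure (match reward > 0 bounds every column score).
* Heuristic search can return two near-identical hits for one locus
  when an indel splits the seed diagonals; deduplication by endpoint
  identity removes these in practice but is not guaranteed to.
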