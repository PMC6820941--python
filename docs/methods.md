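# Methods

`lrstitch` orders and orients draft-assembly contigs using long reads
(PacBio/ONT) that have already been aligned to the contigs by an external
aligner such as BWA-MEM or minimap2.  It consumes alignments, never raw
bases: gaps in the output are runs of `N`, and no consensus or gap filling is
attempted.  This note records the model, the numerical choices, and what the
bundled simulator does and does not establish.

## Coordinate model and alignment revision

All intervals are 0-based with inclusive endpoints; a sequence of length `L`
spans `[0, L-1]`.  SAM's 1-based reference coordinates and clip-aware query
offsets (hard clips counted as read bases) are converted once, at input.
Read coordinates are normalized to the read's original orientation so each
read defines a single axis along which its contigs can be ordered.

Long-read aligners clip noisy alignment ends, so reported intervals
underestimate the true match.  Revision extrapolates each alignment outward,
assuming read and contig advance base-for-base: on the left, whichever
sequence has less unaligned prefix is extended to position 0 and the other
endpoint shifted by the same amount; on the right, symmetric, extending to
the last position (`LEN-1`).  Two consequences of making the shift identical
on both axes:

* the operation is idempotent (a revised alignment revises to itself), and
* the four endpoint displacements are exactly the quantities bounded by the
  reliability threshold α.

The extrapolation is *colinear*: for a reverse-strand alignment the read's
left end pairs with the contig's right end, so the formula is applied in the
mirrored read frame and mapped back.  SAM query coordinates are already
colinear, which is why the frame never needs mentioning when one works
directly on aligner output; it becomes explicit once read coordinates are
normalized to the original orientation.

An alignment is **reliable** when (i) MAPQ > `s_m` (default 20), (ii) both
the read-axis and contig-axis spans exceed `l_m` (default 100 bp), and
(iii) every revision displacement is smaller than `alpha` (default 150 bp).
All comparisons are strict, matching the usual reading of "higher
than"/"greater than"/"smaller than".  Criterion (iii) is what discards
multi-mapping and spuriously clipped records; criterion (i) removes
MAPQ-0 repeat multi-mappers even when they look long.

## Local scaffolds

Each read's reliable alignments, ordered by revised read start, form a local
scaffold: per contig an orientation (1 = forward), a signed gap to the next
contig on the read axis (negative means overlap; never clamped internally),
and the pre-revision read-axis span as alignment length.  Two clean-up rules:

* **End deduplication.**  When several contigs claim the same read end
  (revised interval starting at 0, or ending at `LEN-1`), only the one with
  the greatest alignment length survives; ties break on the smaller contig
  id so output is reproducible.
* **Redundancy pruning.**  A local scaffold holding an adjacent pair (A, C)
  at gap `g` is deleted when another local scaffold orders (A, B, C) with
  matching orientations of A and C and `LEN(B) + gap(B,C) < g`: the longer
  witness explains the gap, and the shorter read almost certainly failed to
  align to B.  The rule is applied to every adjacent pair of every local
  scaffold, and witnesses are recognised in both strand readings (a read
  sampling the opposite strand shows the triple reversed and flipped).

## Contig classification

A collapsed repeat sits in the middle of several reads whose flanks differ,
so it accumulates more than one distinct 5'-end (or 3'-end) neighbour over
its middle-position occurrences (for a reverse-oriented occurrence the
predecessor along the read is the 3'-end neighbour).  A contig is
**ambiguous** when it is shorter than `L_ca` (default 1000 bp), or when it
occurs in a middle position at least once *and* has more than one distinct
neighbour on either end.  Everything else — including contigs no read
touches — is **unique**.  Short contigs are removed from the local scaffolds
before the census and the graph stage, and restored at insertion time.
Neighbour distinctness is by contig id only; orientation is deliberately not
part of the identity (an inverted repeat flank still signals repetitiveness).

## Scaffold graph

Vertices are the unique contigs (unaligned ones included, so they emerge as
singleton scaffolds).  Each local scaffold is projected onto its unique
entries; when entries `p..s` collapse onto the pair `(p, s)`, the projected
gap is the sum of the skipped read-axis gaps plus the lengths of the skipped
contigs.  Every adjacent unique pair contributes one observation: an
orientation type (FF/RR same strand, FR/RF opposite; canonicalized so the
stored edge is independent of read strand and vertex order), a gap, and a
weight equal to the smaller of the two endpoint alignment lengths — the
confidence of a junction is the weaker of its two anchors, not the number of
reads alone.  Per pair, the largest orientation class wins (ties: larger
summed weight, then a fixed type order), the gap is the mean over the
winning class only, and the weight is the class maximum.

## Contradiction removal

Run once over the whole graph, component by component, in three stages:

1. **Orientation (binary program).**  Each vertex gets a strand variable
   `o ∈ {0,1}`, each edge a keep variable `η ∈ {0,1}`.  Opposite-strand
   edges impose `η ≤ o_i + o_j ≤ 2 − η`, same-strand edges
   `η − 1 ≤ o_i − o_j ≤ 1 − η`; the objective maximizes `Σ w·η`.  One vertex
   per component is pinned to `o = 0` (the solution is invariant to a global
   flip).  Edges with `η = 0` are removed.  Solved exactly with
   `scipy.optimize.milp` (HiGHS); `η = 0` everywhere is always feasible.
2. **Position (LP).**  Each vertex gets a coordinate `p`; each edge, directed
   so its tail precedes its head under the solved strands, imposes the big-M
   constraint `L(φ−1) ≤ p_head − p_tail − len(tail) − g ≤ L(1−φ)` with
   `φ ∈ [0,1]` and `L` = component span + total |gap| + 1, making the
   constraint vacuous at `φ = 0`.  Objective `Σ w·φ` — an L1-type layout that
   concentrates residual error on the lightest edges, which is exactly the
   premise that spurious edges carry less read support.  After solving, any
   edge whose realised deviation exceeds `max_gap_deviation` (default
   1000 bp) is removed.  The deviation test uses the realised positions, not
   φ, so degenerate fractional φ cannot mask a contradiction.
3. **End pruning.**  Each edge touches a definite end (5' or 3') of each
   endpoint, determined by its orientation type.  An edge survives only if
   it is the maximum-weight edge at both ends it touches (ties by the other
   endpoint's id); any residual cycle — possible because every vertex may
   still carry one edge per end — is broken at its minimum-weight edge.

The result provably contains only simple paths; this is asserted on every
run, not just in tests.

## Scaffold generation

Draft scaffolds are the maximal simple paths (orientation propagated through
the edge end types; each path is emitted with its first contig forward,
choosing deterministically between the two directions).  Then:

* **Ambiguous insertion.**  For each adjacent unique pair, all local
  scaffolds (both strand readings) are scanned for occurrences of the pair
  separated only by non-unique contigs.  Each distinct oriented run is a
  candidate; the one supported by most local scaffolds wins (ties: larger
  pair weight, then lexicographic), and its gaps are copied from the
  maximal-weight supporting occurrence.  Only non-empty runs compete: a read
  showing the two contigs directly adjacent is evidence about the gap, not a
  competing "empty path".  An ambiguous contig may be inserted at several
  junctions.
* **End extension.**  For each scaffold end, a mini scaffold graph is built
  from only the local scaffolds containing the terminal contig (every contig
  a vertex, same aggregation and contradiction removal), and the simple path
  through the terminal contig extends the scaffold away from its body.  A
  contig already in the scaffold is never re-added, and a unique contig
  already placed in *any* scaffold is never added — this keeps the global
  one-placement guarantee for unique contigs without a repair pass.
  Extension runs one attempt per end per pass, to a fixpoint, capped at 10
  passes.
* **Merging.**  When one scaffold's last `t` parts equal another's first `t`
  parts (ids and orientations; default `t = 2`), they merge, averaging the
  gaps inside the overlap; the reversed orientation of the second scaffold
  is also attempted.  Repeated to fixpoint with a deterministic processing
  order.  `t = 1` would merge on a single shared contig, which is aggressive;
  2 is the shipped default and is user-settable.

Output: a scaffold FASTA in which oriented contig sequences are separated by
`max(round(gap), 1)` `N` characters, plus a layout TSV that preserves the
signed, unclamped gap estimate (a negative estimate means the contigs likely
overlap; the sequence file still shows a single `N` separator).

## Parameters

| name | default | unit | meaning |
|------|---------|------|---------|
| `s_m` | 20 | MAPQ | minimum mapping quality, exclusive |
| `l_m` | 100 | bp | minimum aligned span on read and contig, exclusive |
| `alpha` | 150 | bp | maximum revision displacement, exclusive |
| `L_r` | 500 | bp | minimum read length, exclusive |
| `L_c` | 200 | bp | minimum contig length, exclusive |
| `L_ca` | 1000 | bp | contigs shorter than this are ambiguous outright |
| `t` | 2 | contigs | terminal overlap required to merge scaffolds |
| `containment_fraction` | 0.95 | — | coverage above which a contig inside a longer one is dropped (needs contig-vs-contig alignments) |
| `max_gap_deviation` | 1000 | bp | positional deviation above which an edge is spurious |

`s_m`, `l_m` and `alpha` defaults follow standard practice for noisy long
reads.  `L_r`, `L_c`, `L_ca`, `t` and the containment fraction have no
canonical values and are deliberately user-facing; the defaults were chosen
once so that reliable alignments can exist (`l_m < L_c`) and a 1 kb
ambiguity cutoff separates fragments from placeable contigs at typical draft
contiguity.  Containment detection is optional input rather than computed
internally, because how "completely contained" is established is an
alignment-pipeline concern, not a scaffolding one.

## The simulator

The generator emulates pipeline inputs at the alignment level.  A genome is
built from oriented contig sequences (random orientation per contig)
separated by 50–200 bp of unassembled sequence; reads of 3–8 kb are sampled
uniformly from both strands at the requested coverage; and each
sufficiently-overlapped contig interval yields one SAM record.  Read error
is abstracted as endpoint jitter (`coord_noise`, clamped to valid
intervals), record dropout (`p_missing`), and MAPQ degradation.  Repeats:
the default representation is the *collapsed* one — a single contig holding
the repeat unit, placed at several genome positions with high-MAPQ records —
which is what an assembler actually emits for an exact repeat and what the
classifier is designed to detect.  A standalone mode (one contig per copy,
records assigned to a random copy with low MAPQ) is available for studying
the multi-mapping regime, where the copies are filtered out by the
reliability criteria instead of being classified.

Presets: `clean` (100 kb, 20 contigs, 20×, no noise), `noisy`
(`coord_noise = 100 < alpha`, `p_missing = 0.1`), `repeat` (3 exact copies of
a 2 kb unit).  One seed fixes all randomness; outputs are byte-identical
across runs.

What passing on these presets shows: the geometry of the pipeline — ordering,
orientation, gap estimation, repeat detection by neighbour multiplicity —
is correct under endpoint-level noise bounded by α.  What it does not show:
behaviour under base-level error models, chimeric reads, heterozygosity,
inexact repeats, or aligner-specific clipping pathologies; none of these is
emulated.

## Numerical and determinism notes

* Both programs are solved exactly per connected component; a warning is
  logged for components beyond ~2000 vertices, but they are still solved
  exactly.
* The LP/ILP backend (HiGHS) is deterministic; every iteration order in the
  package is sorted, and all ties (end dedup, orientation vote, end pruning,
  cycle breaking, candidate insertion, scaffold naming) break on explicit
  deterministic keys, so identical inputs give byte-identical outputs.
* Gap estimates are carried as signed floats end to end and only clamped at
  FASTA rendering.
* The one-scaffold-per-component walk, the anchor `o = 0`, and the anchor
  `p = 0` make solutions unique only up to a global flip per component;
  consumers (path extraction, truth comparison in tests) are written to be
  flip-invariant.

## Known limitations

* Scaffolding quality degrades when junction coverage is low: a junction
  spanned by no reliable alignment pair cannot be recovered (the simulator's
  presets keep expected junction coverage well above 1).
* The redundancy-pruning rule deletes whole local scaffolds, as specified,
  rather than single pairs; with very long reads this can discard useful
  distal pairs along with the redundant one.
* Exact-repeat collapsing is assumed; near-identical repeats that the
  assembler kept as separate contigs appear as multi-mapping alignments and
  are handled by the MAPQ filter, not the classifier.
* Runtime scales with the number of alignments and the ILP component sizes;
  the design targets bacterial-to-small-eukaryote drafts.
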