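# Methods

## Model and assumptions

The clustering operates entirely in a 48-dimensional integer composition
space.  A read contributes, for each ordered base pair (b₁, b₂) over
{A,C,G,T} and each gap g ∈ {0,1,2}, the count of positions i with
seq[i] = b₁ and seq[i+1+g] = b₂.  For a pure-ACGT read of length L the
counts sum to (L−1)+(L−2)+(L−3); the embedding is order-sensitive
(reversal changes it) and deliberately alignment-free.  Its key property
for pyrosequencing data is that a single insertion, deletion or
substitution moves a point by only ≈3.3–3.5 Euclidean units regardless of
read length — the same scale as the clustering thresholds — whereas
unrelated reads of ITS1-like composition sit tens of units apart.  The
method assumes reads are globally comparable amplicons of one locus
(roughly 50–300 nt); it is not meant for shotgun fragments of varying
origin, where composition similarity no longer tracks homology.

Two distinct reads *can* in principle share a vector; such reads are
treated atomically (they cannot be split across clusters), which is the
behaviour wanted for true duplicates and harmless for rare coincidences.

Clustering is density-based single linkage: at a distance threshold d,
points connect when their squared distance is ≤ d², and a connected
component is a valid cluster when it carries at least N sequences
(multiplicities included).  No constraint is placed on cluster shape and
there is no notion of a cluster center.  Sweeping an increasing threshold
schedule yields births, growth and merges, recorded as a forest; the
leaves are the final clusters.  Each leaf's *seed* — its state just before
its first merge — anchors the post-hoc re-assignment of sequences that
entered the hierarchy later, each going to the leaf holding its nearest
seed sequence.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N (`min_cluster_size`) | 100 sequences | density constraint for a valid cluster, and the final size filter; clusters below it are pooled into the noise |
| schedule start d₁ | 3.317 | just above the displacement caused by a single sequencing error, so level-1 clusters are sets of reads within ~one error of each other |
| schedule end d_K | 7.141 | ≈ two error-scale units; beyond this, composition proximity stops being persuasive evidence of identity |
| levels K | 23 | granularity of the hierarchy; more levels refine entry levels and merge ordering, not the final leaves' existence |
| error model | 0.18; 0.61/0.17/0.22; 0.46/0.33/0.21 | fraction of reads mutated; 1/2/3-error probabilities; insertion/deletion/substitution probabilities (typical 454 statistics) |

Interpolation of the schedule between its endpoints is linear in *squared*
distance, the algorithm's native integer scale.  An explicit level list
can be supplied instead (e.g. alternate starting levels such as 3.464,
3.606, 3.873, 4.000, 4.243 — these are exactly the displacements of small
sequence edits in this space).

## Numerical choices

- All threshold comparisons are `integer squared distance ≤ d²`; no
  floating-point distance is ever compared, so results are bit-stable.
  Pairwise squared distances are computed exactly in int64 via the
  polarization identity, in row blocks so the full matrix never
  materializes.
- Determinism and order invariance: points are sorted canonically (by
  vector coordinates), edges are processed sorted by (distance, i, j), and
  cluster ids are assigned per level in order of each component's smallest
  member id.  Two runs on any permutation of the input are byte-identical.
- Re-assignment tie-break: a sequence exactly equidistant from several
  seeds goes to the smallest cluster id.
- Reference retention cutoff: a reference is kept iff its nearest
  classified sequence lies within the last (loosest) schedule level; its
  entry level is the smallest level admitting that distance.  Sequences
  re-assigned post hoc keep the entry level at which they first joined any
  valid cluster, which is the quantity meant by "entered the
  classification".
- Ambiguity codes: any pair touching a non-ACGT character is skipped.
  This keeps vectors integer and well-defined; heavily ambiguous reads
  drift toward the origin and typically end in the noise, which is the
  conservative outcome.  Reads shorter than 4 nt are encoded (with empty
  gap classes) under a logged warning.
- Alignment: percent divergence uses unit-cost Needleman–Wunsch
  (match 0, mismatch 1, gap 1) with the identity denominator equal to all
  alignment columns, gaps included.  Among co-optimal alignments the
  match count is maximized, then mismatches are preferred over gap pairs,
  making reported divergences deterministic.  A pairwise aligner was
  chosen over a multiple alignment for radius computation: it is exact per
  pair and dependency-free; radii of clusters with many indels can differ
  slightly from an MSA-based estimate.
- ARI degenerate case (expected index equal to the maximum index, e.g.
  both partitions all singletons): defined as 1 when the groupings are
  identical, else 0.
- Error simulation: error positions are uniform over the current string
  and errors apply sequentially (an error can hit an already-mutated
  base); deleting from a length-1 read re-draws the error type.
  Homopolymer-length bias is not modeled — the model is specified only by
  error counts and types.

## Synthetic data generator

`generate_families` emulates the structure the clustering assumes: F
ancestors drawn uniformly over ACGT with lengths uniform in 100–300 nt
(the ITS1 length scale), each diversified into members by per-base
substitutions (default rate 0.01) and rare indels (default 0.002), plus
unrelated random background reads labeled noise.  Defaults (3 families ×
150 members, 200 noise reads) put families comfortably above N = 100 and
leave zero-mutation duplicates in each family, exercising point
multiplicity.  With these rates the maximum intra-family distance stays
below the minimum inter-family distance (asserted in tests), so family
recovery is a well-posed check.

What the generator does **not** emulate: chimeras and primer artifacts,
length-dependent error rates, homopolymer-biased indels, compositional
biases of real ITS1 (real sequences are not uniform-random), or uneven
family abundances.  Passing the recovery and robustness tests therefore
demonstrates the machinery is correct and stable under the modeled error
process, not that any particular OTU delineation of real communities is
biologically right.

## Problem sizes

The test-suite and acceptance runs use desk-scale datasets chosen to make
every check exact or statistically sharp: hundreds of reads (≤ ~1,000
points) for clustering, where brute-force oracles remain feasible; 10,000
simulated reads for recovering the error-model percentages (3 binomial
standard errors ≈ ±1.2 points on the 18% selection rate); 100,000 for the
chi-square goodness-of-fit of error counts and types.  The clustering core
is O(n²) in distinct vectors per run plus near-linear level sweeps, and
the radius statistic is O(s²·L²) per cluster, so both scale far beyond
these sizes, but exactness of the oracles — not throughput — dictated the
test scale.

## Known limitations

- The level schedule between the endpoints is a design choice
  (linear-in-d²); hierarchies built with a different spacing have the same
  leaves for well-separated data but can time merges differently.
- Single linkage chains: two genuinely distinct but bridged families merge
  at the bridging level; the seed mechanism preserves their identities as
  separate leaves, which is the intended behaviour, but entry levels of
  bridge reads are attributed to the merge level.
- Memory for the edge list grows with the number of point pairs within
  d_K; extremely dense datasets (many near-duplicate vectors) are better
  served by raising N or lowering d_K.
- No multiple sequence alignment, taxonomic annotation or chimera
  detection is provided.
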