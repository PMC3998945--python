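# Methods

## Problem and scoring

netquery computes a global pairwise alignment of a query PPI network
G1 = (V1, E1) to a target network G2 = (V2, E2).  An alignment is a partial
injective map a: V1 → V2 restricted to candidate pairs, i.e. pairs whose
all-against-all sequence-alignment E-value is at most a cutoff E_max
(non-strict; the cutoff 0 admits pairs whose E-value underflowed to
exactly zero, as BLAST reports for very strong hits).  Pairs absent from
the similarity table are forbidden at every cutoff — the alignment is only
defined over pairs for which an E-value was computed.

The primary objective is **edge correctness**
t(a) = (conserved query edges) / min(|E1|, |E2|), and the total score adds
a sequence term

    s(a) = t(a) + c · Σ_u b(u, a(u)),   c = 1 / ((1 + min|E|) · min|V|),

with b(u, v) ∈ [0, 1] the normalized bit score.  Since Σ b over mapped
nodes is at most min|V|, the sequence term is bounded by
1/(1 + min|E|) < 1/min|E|: it can never outweigh one conserved edge, so
maximizing s is exactly lexicographic optimization of (edge correctness,
total bit score).  The test suite verifies this subordination and the
lexicographic equivalence by exhaustive enumeration on small random
instances.

Both networks are confidence-filtered before any score is computed: edges
with confidence strictly above c_min are kept ("above" read strictly, so
c_min = 0 keeps every positive-confidence edge).  Edge and node counts in
the score refer to the filtered networks.  The default c_min is 0.1.

**Bit-score normalization.**  Raw bit scores are divided by the largest
raw bit score in the similarity table, so the best pair gets exactly 1.0.
No standard definition of the normalization exists; dividing by the global
maximum is instance-intrinsic, order-preserving and guarantees b ∈ [0, 1].
An alternative — dividing each score by the query protein's self-alignment
score — would need self-hits that user-supplied tables often lack, and is
therefore not implemented.  The choice only affects tiebreaking among
alignments of equal edge correctness, never the topology objective.

## Exact solver and certificates

Maximizing s(a) generalizes the quadratic assignment problem.  We solve a
standard linearization exactly:

* binary variables x(u, v) per candidate pair with row/column injectivity
  constraints (each query node maps to at most one target node and vice
  versa);
* one conservation variable y per (query edge uv, target edge pq) that at
  least one orientation of candidate choices can realize, constrained by
  y ≤ Σ x on the u side and y ≤ Σ x on the v side (the sums range over the
  feasible orientations).  Under injectivity, y can be 1 exactly when uv
  maps onto pq, so y is left continuous in [0, 1] and takes integral
  values at any integral x;
* objective (Σ y)/min|E| + c · Σ b(u, v) x(u, v).

The program is solved by HiGHS through `scipy.optimize.milp` with a zero
relative-gap target and a per-cutoff time limit (default 300 s).  The
engine's best dual bound is reported as a certified **upper bound** on the
optimal score; the difference between bound and incumbent is the
**optimality gap**, with gap ≤ 1e-6 declared optimal.  On query-scale
instances (tens of query nodes, candidate lists limited by the E-value
cutoff) the gap closes and optimality is proven; on time-limit expiry the
incumbent and the best proven bound are returned with `optimal = False`.
The reported score is always recomputed independently from the returned
mapping, never read off the engine's objective value.  HiGHS runs
single-threaded and deterministically, and all orderings (variables,
output rows) are fixed lexicographically, so repeated runs are
byte-identical.

Nodes never need to be mapped: since b ≥ 0, mapping a candidate-bearing
node cannot decrease the score, so optima are effectively maximal; the
solver reports whichever optimal mapping the engine certifies.

**Sequence-only mode** drops topology and maximizes Σ b alone — a
maximum-weight bipartite assignment solved exactly with
`scipy.optimize.linear_sum_assignment` on the candidate weight matrix.
Forbidden pairs carry weight zero and are stripped from the returned
assignment afterwards; because all weights are non-negative, this is
lossless (any matching extends to a full assignment through zero-weight
cells without changing its value).  The result is always provably optimal
(gap 0).

**Brute-force oracle.**  `brute_force_align` enumerates every partial
injective map consistent with the candidate set (guarded to at most 1e7
feasible mappings) and is used purely as an independent oracle in tests;
30 seeded random instances per mode are checked for exact score agreement.

## Numerical conventions

Score equality is judged at 1e-12 absolute; solver optimality at gap
≤ 1e-6; bound validity at 1e-9.  Ties in the brute-force oracle are broken
toward the lexicographically smallest mapped-pair list.  Degenerate
inputs: an empty candidate set yields the empty alignment with a warning
status (score 0, bound 0) rather than an error; a network with no edges
after filtering makes edge correctness undefined and aborts the pipeline
with a stage-named error; duplicate edges keep the maximum confidence and
self-loops are dropped with a logged warning.

## Input formats

Edge list (2-3 whitespace columns, optional numeric confidence third
column, `#` comments and single-token isolated-node lines allowed),
Cytoscape SIF, IntAct MITAB (columns 1-2 as identifiers with database
prefixes stripped, column 15 scanned for a `score:x` confidence), and
STRING protein-links text (integer combined score divided by 1000, per
STRING's 0-999 convention).  Detection is structural — column counts, a
non-numeric SIF interaction-type column, MITAB's ≥ 15 tab-separated
columns, STRING's header — never the file extension.  A headerless
three-column file with integer third column is read as STRING; an
ambiguous single-row file like `A B 1` therefore parses as STRING, which
is documented here as the one unavoidable dialect collision.  Edges
without a stated confidence (SIF, two-column edge lists) default to 1.0.
Node identifiers are exact case-sensitive strings; no cross-referencing
against external protein databases is performed.

## Wnt fixture

The packaged example query network models the canonical Wnt signaling
pathway with 11 proteins (WNT1, A2MR, FZD1, DVL1, AXIN1, GSK3B, CTNNB1,
APC, TCF7, TLE1, MYC) and 17 interactions: the WNT1/FZD1/A2MR
ligand-receptor triangle, FZD1-DVL1, DVL1's inhibitory contacts with
GSK3B/AXIN1/APC, the four-protein degradation-complex clique
(GSK3B/AXIN1/APC/CTNNB1), CTNNB1-TCF7, TCF7-TLE1, and the induction edges
TCF7-MYC and CTNNB1-MYC.  The protein set and the 11-node/17-edge counts
are fixed by the pathway description; the specific edge list is a
reconstruction of the described interactions, so tests assert the counts
and the member set, never individual reconstructed edges.

## Synthetic benchmark generator

`generate_planted` emulates a cross-species query: an Erdős–Rényi query
graph (default 8 nodes, edge probability 0.3) embedded into a larger
target (default 20 nodes) under a known injection, with each embedded edge
independently deleted with probability `rewire_rate` (default 0.1,
modelling interactions lost or undetected in the other species) and
background edges added at the same edge probability among node pairs not
both truth-images.  The similarity table gives each true pair a top bit
score (100, perturbed by relative Gaussian noise `bit_noise`, default
0.1) and each query node `decoys_per_node` (default 3) lower-scoring decoy
candidates; with `inflated_decoy_rate > 0` some decoys outscore the true
pair, emulating a sequence-wise closer but topologically wrong homolog —
the regime in which topology mode demonstrably conserves more interactions
than sequence-only alignment.  E-values are derived from bit scores by the
fixed monotone map E = 10^(−bits/5); the map is arbitrary (real E-values
depend on database size) but order-consistent and spreads pairs across the
default cutoff ladder so candidate nesting is exercised.

What the generator does *not* emulate: scale-free/duplication-divergence
degree distributions, confidence-correlated interaction noise, paralogous
families with many near-equal bit scores, or realistic E-value statistics.
Passing the planted-recovery tests therefore demonstrates correctness of
the optimization and the scoring machinery under controlled noise, not
performance on real interactomes.

Default problem sizes throughout the test suite (queries of 4-8 nodes,
targets up to 20, 20-30 seeded replicates) were chosen so that exhaustive
oracles remain feasible and the whole suite completes in seconds while
still exercising every code path at meaningful noise levels.

## Known limitations

* The solver targets query-scale instances; interactome-vs-interactome
  alignment (millions of edge-pair variables) is out of scope.
* The candidate-pair model is hard: a query node with no similarity entry
  below the cutoff can never be aligned, even if topology strongly
  suggests a partner.
* SIF cannot express confidences, and edge lists cannot express node
  descriptions; round-trips through those formats preserve only what the
  format can carry.
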