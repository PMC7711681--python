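# Methods

## Objects and encoding

The package enumerates connected multigraphs with a tree skeleton, `n`
vertices, `delta` self-loops and no multiple edges, up to isomorphism.
Cycle rank equals `delta` for this class, since each self-loop is an
independent cycle and the skeleton is acyclic.

A rooted graph with a fixed left-to-right order on children (an *ordered
loop-tree*) is encoded by its sequence representation: index vertices in
sibling-depth-first (SDFS) order — root first, siblings consecutive, each
vertex's descendant block contiguous — and list, for positions `2..n`, the
pair `(subtree vertex count, subtree loop count)`. SDFS makes the encoding
recursive: the first `d` entries are the root-subtree sizes, followed by
the root-subtrees' own encodings in order. A sequence arising this way is
*admissible*; admissibility is a prefix-sum recursion checkable in O(n),
and the ordered graph is rebuilt uniquely from an admissible sequence in
O(n). Loop counts are only constrained by `sum(b_i) <= delta` at every
level: the root absorbs whatever its subtrees do not account for, so the
sequence never stores root loop counts explicitly.

The *canonical representation* of a rooted graph is the lexicographically
maximum admissible sequence over all child orderings (pairs compare vertex
count first, then loop count; a proper prefix is smaller). It is computed
bottom-up by sorting children on the key `(subtree vertices, subtree
loops, child's canonical sequence)` in non-increasing order; ties among
fully equal keys are left stable, which cannot change the output. A
sequence is canonical iff at every level (i) the `a_i` are non-increasing,
(ii) `b_i >= b_{i+1}` whenever `a_i = a_{i+1}` and `sum(b_i) <= delta`,
and (iii) each root-subsequence is recursively canonical and
non-increasing across runs of equal `(a_i, b_i)` pairs.

## Predecessor walk

`M(n, delta)`, the set of canonical sequences, is enumerated by walking
the immediate-predecessor relation from its maximum
`((n-1, delta), (n-2, delta), ..., (1, delta))` (path, loops on the
deepest leaf) down to its minimum `((1,0), ..., (1,0))` (star, loops on
the root). The predecessor of `M` with root degree `d`:

* if some root-subsequence is non-minimal, take the last such slot `k`,
  replace `M(k)` by its own predecessor, copy that across the whole run of
  slots whose `(a, b)` pair equals slot `k`'s (condition (iii) caps them
  there, and equality maximises), and reset all later subsequences to
  their maxima;
* otherwise every root-subsequence is the star and only the root block can
  decrease: drop at the **last** slot `j` whose pair is not `(1, 0)` —
  decrement `b_j` if positive, else decrement `a_j` and hand that slot the
  entire remaining loop budget — then refill the suffix of the block
  greedily (largest vertex count allowed by the non-increasing constraint
  and the remaining vertex budget, then largest loop count allowed by the
  equal-`a` cap and the remaining loop budget), and set all subtrees to
  their maximum sequences;
* if every root pair is `(1, 0)` the sequence is the minimum and has no
  predecessor.

Each step is O(n) amortized (the case-analysis scans are linear and the
recursion is bounded by subtree size), and by construction the output
satisfies the canonicality conditions, so the walk needs no
validate-and-reject loop. The greedy block refill is a deliberate design
choice over a fixed-vertex-profile rule: keeping the vertex profile
whenever some `b_i > 0` skips sequences in which a later loop-free slot
could still shed a vertex (smallest witness: stepping down from
`((2,1),(2,0),(1,0),(1,0))` at `n = 5`, `delta = 1` must yield
`((2,1),(1,0),(1,0),(1,1))`, which changes the vertex profile at slot 2
while slot 1 keeps its loop). Exhaustive gap-freeness tests against a
brute-force construction oracle (all `n <= 7`, `delta <= 3`) pin the rule
down; the case-(d) recursion uses explicit descend/rebuild frames so
interpreter recursion limits never matter (contract: path inputs up to
`n = 10**5`).

## Unrooted enumeration

Every free tree has either a unicentroid or (even `n` only) a bicentroid,
so rooting there picks one canonical root per unrooted class:

* unicentroid classes are exactly the canonical sequences whose root
  subtrees all have at most `m = floor((n-1)/2)` vertices. Because the
  vertex profile is non-increasing, these form a contiguous *suffix* of
  the predecessor chain; the walk simply starts at the largest such
  sequence, `((m, delta), (m, 0)) + L(m, delta) + L(m, 0)` for odd `n`
  (with an extra `(1, 0)` slot for even `n`), where `L` denotes the
  maximum sequence.
* bicentroid classes are unordered pairs of rooted halves on `n/2`
  vertices joined root-to-root: loop splits `b1 + b2 = delta` with
  `b1 >= b2`, halves `M1 in M(n/2, b1)`, `M2 in M(n/2, b2)`, restricted to
  `M1 >= M2` when `b1 = b2`. This nested iteration generates the same set
  as a specialised predecessor chain on composite sequences would, at the
  same per-output cost, without a second predecessor variant. Counting
  combines the lengths of the half chains (`N1*N2`, triangular when
  `b1 = b2`); the halves themselves still come from the predecessor walk —
  no closed-form counting is used anywhere.

`n = 1` is the single vertex carrying all loops; `n = 2` is entirely
bicentroid (the unicentroid bound `m = 0` empties that branch).

## Polymer filter and census

A self-loop adds 2 to its vertex's degree (standard multigraph
convention), so the filter keeps a graph iff every vertex has
`skeleton_degree + 2*loops >= 3`. The convention is corroborated
structurally: the single vertex qualifies iff `delta >= 2`, and the
two-vertex census row equals `floor(rank/2)` (loop splits with both sides
>= 1), both matching the reference census. A polymer topology with `n`
vertices needs rank `>= ceil(n/2) + 1` (each vertex needs degree 3 from
`n-1` skeleton edges plus `delta` loops), so the per-rank census runs
`n = 1 .. 2*(rank-1)`; the support bound is verified against the census
table's zero pattern rather than assumed. Unicentroid items are filtered
on the reconstructed graph; for bicentroid items each half is summarised
once (interior degrees valid; root degree valid given the joining edge)
and pairs are combined from those summaries, which the tests check against
filtering the realised stream.

## Oracle and fixtures

The test oracle is construction-based and shares no logic with the walk:
skeletons from `networkx.nonisomorphic_trees` (cross-checked against an
exhaustive Prüfer-sequence sweep of all labelled trees for `n <= 6`), all
rootings, all loop compositions, deduplicated by the canonicalizer —
whose own correctness is tested separately against the brute-force
maximum over all child orderings and against permutation-based rooted
isomorphism (`networkx.is_isomorphic` with root and loop-count node
attributes). Unrooted oracle keys are the maximum over all rootings of
the rooted canonical sequence, deliberately *not* centroid rooting, so
enumerator and oracle cannot fail identically. Oracle sizes are capped at
`n <= 7`, `delta <= 6`; beyond that the space is superexponential.

Random fixtures (`random_loop_tree`) draw a uniform Prüfer skeleton, a
uniform root, a uniform loop placement and shuffled child orders from a
single explicitly seeded stream; the same `(n, delta, seed)` always yields
the same tree. These emulate arbitrary valid inputs exactly — the objects
here are combinatorial, so unlike noisy-data generators there is no
fidelity gap between synthetic and "real" inputs; what the tests do *not*
probe is performance at extreme sizes (`n` in the tens of thousands is
covered only by two smoke tests).

## Numerical/engineering notes

* All quantities are exact integer counts; there are no tolerances,
  floating-point steps or convergence criteria anywhere.
* Sequences are plain tuples of int pairs; Python's tuple ordering *is*
  the required lexicographic order, so comparisons in hot loops are
  C-speed.
* Problem sizes used by the shipped checks — up to `(10, 10)` with
  3,488,567 classes for plain counting and `(9, 9)` with 429,496 realised
  graphs for the filtered census — were chosen to keep a full validation
  run in the tens of seconds on one CPU; the enumeration itself is
  unbounded and streams lazily.
* Known limitations: no successor operation (the walk is top-down only);
  no non-tree skeletons or multiple edges, so the rank-`r` census covers
  the tree-like subset of polymer topologies only; counting is by
  enumeration, so counts cost time proportional to their value (the
  dynamic-programming alternative is out of scope by design).
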