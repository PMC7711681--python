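# looptree

Isomorph-free, exhaustive enumeration of connected multigraphs whose
skeleton is a tree — *n* vertices, Δ self-loops, no multiple edges — and,
as the main application, a census of **tree-like polymer topologies of a
given cycle rank**.

## Why

A polymer topology is what is left of a chemical compound after repeatedly
deleting all vertices of degree ≤ 2: a connected multigraph with every
vertex of degree ≥ 3. Polymer topologies are classified by cycle rank
(the number of edges whose removal leaves a spanning tree), and a graph
with a tree skeleton, Δ self-loops and no multiple edges has cycle rank
exactly Δ. Enumerating all such graphs — exactly one representative per
isomorphism class, with no invalid intermediate structures — therefore
gives every tree-like polymer topology of rank Δ after a simple degree
filter. That is useful for cataloguing macromolecular architectures and
for structure generation in cheminformatics.

## How it works

Every **rooted** graph of this class is identified with a canonical
sequence: order each vertex's children, index the vertices in
sibling-depth-first (SDFS) order, and record for SDFS positions 2..n the
pair (subtree vertex count, subtree loop count). Over all child orderings,
the lexicographically maximum such sequence — the *canonical
representation* — is a complete invariant of the rooted isomorphism class,
and the graph is rebuilt from it in O(n) time. Writing M(n, Δ) for the set
of canonical sequences, enumeration is a walk: start from the maximum of
M(n, Δ) (the rooted path with all loops on the deepest leaf) and repeatedly
apply an O(n) *immediate predecessor* operation until the minimum (the star
with all loops on the root). Each step emits one class; nothing is ever
generated and discarded.

**Unrooted** classes are obtained by centroid rooting: trees with a
unicentroid are exactly the canonical sequences whose root subtrees all
have ≤ ⌊(n−1)/2⌋ vertices (a contiguous suffix of the same predecessor
chain), and for even *n* the bicentroid classes are unordered pairs of
rooted halves of n/2 vertices each, joined root-to-root, with the loop
budget split between the halves.

## Worked example

How many non-isomorphic graphs have a tree skeleton, 4 vertices and 1
self-loop — and what are they?

```
$ looptree count --n 4 --loops 1
4
$ looptree enumerate --n 4 --loops 1
# n=4 loops=1 mode=unrooted
1 2
1 3
1 4
2 2

# n=4 loops=1 mode=unrooted
1 2
1 3
1 4
1 1

# n=4 loops=1 mode=unrooted
1 2
1 3
3 4
2 2

# n=4 loops=1 mode=unrooted
1 2
1 3
3 4
1 1
```

Four classes: the star with the loop on a leaf, the star with the loop on
the center, and the path with the loop on an inner vertex or on an end
vertex (the last two are emitted as bicentroid pairs — vertices 1–2 are one
half, 3–4 the other, with 1–3 the joining edge). Lines `u v` with `u ≠ v`
are skeleton edges, `v v` lines are self-loops.

The polymer census for cycle rank 4 — all tree-like polymer topologies
with 4 independent cycles:

```
$ looptree census --rank 4
   n  rank count
   1     4    1
   2     4    2
   3     4    2
   4     4    3
   5     4    2
   6     4    1
     total   11
```

Eleven topologies in total, e.g. the single vertex with four loops (n=1)
and, at the other extreme, the unique 6-vertex tree whose every vertex
reaches degree 3 with one loop apiece minus the two spent on the skeleton.

Library use mirrors the CLI:

```python
>>> from looptree import count, census, enumerate_unrooted
>>> count(5, 9)
856
>>> census(4).total()
11
```

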