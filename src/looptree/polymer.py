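"""Tree-like polymer topologies of a given cycle rank.

A polymer topology is a connected multigraph in which every vertex has
degree at least three (what remains of a chemical compound after
iteratively deleting degree <= 2 vertices).  A graph with a tree skeleton,
``delta`` self-loops and no multiple edges has cycle rank exactly
``delta``, so filtering the unrooted enumeration by the degree condition
yields every tree-skeleton polymer topology of rank ``delta``.

A self-loop contributes 2 to its vertex's degree (standard multigraph
convention); the degree of vertex ``v`` is therefore
``skeleton_degree(v) + 2 * loops(v)``.  A polymer topology with ``n``
vertices needs rank at least ``ceil(n/2) + 1``, so the per-rank census runs
``n`` from 1 to ``2 * (rank - 1)``.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .enumerator import UnrootedClass, _loop_splits, _unicentroid_sequences, enumerate_rooted
from .model import CensusReport, OrderedLoopTree, RootedLoopTree
from .seqrep import build_graph

__all__ = ["is_polymer", "is_polymer_tree", "count_polymer", "census"]


def _degrees_ok(tree: OrderedLoopTree, extra_root_degree: int = 0) -> bool:
    """Every vertex has skeleton degree + 2*loops >= 3.

    ``extra_root_degree`` accounts for the joining edge when the tree is one
    half of a bicentroid composite.
    """
    base = tree.base
    loops = base.loops
    for v in base.vertices():
        deg = len(tree.children(v))
        if v != base.root:
            deg += 1
        else:
            deg += extra_root_degree
        if deg + 2 * loops.get(v, 0) < 3:
            return False
    return True


def is_polymer_tree(tree: RootedLoopTree | OrderedLoopTree) -> bool:
    """Degree filter for a plain rooted loop-tree."""
    if isinstance(tree, RootedLoopTree):
        tree = OrderedLoopTree(
            base=tree,
            children_order={v: tuple(c) for v, c in tree.children_map().items()},
        )
    return _degrees_ok(tree)


def is_polymer(item: UnrootedClass) -> bool:
    """Degree filter for an unrooted enumeration item.

    Reconstructs the graph(s) from the sequence(s) and checks that every
    vertex has multigraph degree >= 3.
    """
    if item.kind == "unicentroid":
        tree = build_graph(item.seq, item.n, item.delta)
        return _degrees_ok(tree)
    (h1, b1, m1), (h2, b2, m2) = item.halves
    return _degrees_ok(build_graph(m1, h1, b1), extra_root_degree=1) and _degrees_ok(
        build_graph(m2, h2, b2), extra_root_degree=1
    )


def _half_polymer_count(h: int, b: int, cache: Dict[Tuple[int, int], int]) -> int:
    """Number of rooted halves in M(h, b) that stay polymer-valid once their
    root gains the joining edge."""
    key = (h, b)
    if key not in cache:
        good = 0
        for m in enumerate_rooted(h, b):
            if _degrees_ok(build_graph(m, h, b), extra_root_degree=1):
                good += 1
        cache[key] = good
    return cache[key]


def count_polymer(n: int, rank: int) -> int:
    """Number of tree-skeleton polymer topologies with ``n`` vertices and
    cycle rank ``rank`` (= ``rank`` self-loops, no multiple edges)."""
    if n < 1 or rank < 0:
        raise ValueError("n >= 1 and rank >= 0 required")
    if n == 1:
        return 1 if rank >= 2 else 0
    total = 0
    for seq in _unicentroid_sequences(n, rank):
        if _degrees_ok(build_graph(seq, n, rank)):
            total += 1
    if n % 2 == 0:
        h = n // 2
        cache: Dict[Tuple[int, int], int] = {}
        for b1, b2 in _loop_splits(rank):
            g1 = _half_polymer_count(h, b1, cache)
            if b1 == b2:
                # the qualifying halves keep their relative order, so each
                # unordered qualifying pair appears exactly once
                total += g1 * (g1 + 1) // 2
            else:
                total += g1 * _half_polymer_count(h, b2, cache)
    return total


def census(rank: int) -> CensusReport:
    """Per-vertex-count polymer census for one cycle rank.

    Covers ``n = 1 .. 2*(rank - 1)``, outside of which no tree-skeleton
    polymer topology of this rank exists.
    """
    if rank < 2:
        raise ValueError("rank must be >= 2 (no polymer topology below rank 2)")
    rows = {(n, rank): count_polymer(n, rank) for n in range(1, 2 * (rank - 1) + 1)}
    return CensusReport(mode="polymer", parameters=(rank,), rows=rows)
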