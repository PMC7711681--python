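"""Brute-force ground truth and random fixtures, for testing only.

Everything here is deliberately independent of the predecessor/enumerator
machinery: rooted classes come from exhaustive tree skeletons x rootings x
loop placements deduplicated by :func:`looptree.canonical.canonicalize`,
and unrooted classes are keyed by the *maximum over all rootings* of the
rooted canonical sequence -- sharing no logic with the centroid rooting the
enumerator uses.  Sizes are guarded: the search space is superexponential.

Skeletons are taken from :func:`networkx.nonisomorphic_trees`; for small
``n`` an additional Pruefer-sequence sweep over all labelled trees
cross-checks that list (:func:`all_labeled_trees`).
"""

from __future__ import annotations

import itertools
import random
from typing import Dict, Iterator, List, Sequence, Set, Tuple

import networkx as nx

from .canonical import canonicalize
from .model import OrderedLoopTree, PairSeq, RootedLoopTree

__all__ = [
    "brute_rooted_classes",
    "brute_unrooted_classes",
    "random_loop_tree",
    "all_labeled_trees",
    "tree_from_edges",
    "unrooted_key",
]

_MAX_N = 7
_MAX_DELTA = 6


def _guard(n: int, delta: int) -> None:
    if n > _MAX_N or delta > _MAX_DELTA:
        raise ValueError(
            f"oracle limited to n <= {_MAX_N}, delta <= {_MAX_DELTA} "
            "(combinatorial explosion)"
        )


def _compositions(total: int, parts: int) -> Iterator[Tuple[int, ...]]:
    """All ways to write ``total`` as an ordered sum of ``parts`` >= 0."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def tree_from_edges(
    n: int, edges: Sequence[Tuple[int, int]], root: int, loops: Dict[int, int]
) -> RootedLoopTree:
    """Root an undirected tree (vertices 1..n) at ``root``."""
    adj: Dict[int, List[int]] = {v: [] for v in range(1, n + 1)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    parent: Dict[int, int] = {}
    stack = [root]
    seen = {root}
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                parent[w] = v
                stack.append(w)
    return RootedLoopTree(
        n=n, root=root, parent=parent, loops={v: loops.get(v, 0) for v in adj}
    )


def _skeletons(n: int) -> List[List[Tuple[int, int]]]:
    """Edge lists (1-based) of all free trees on ``n`` vertices."""
    if n == 1:
        return [[]]
    if n == 2:
        return [[(1, 2)]]
    out = []
    for g in nx.nonisomorphic_trees(n):
        out.append([(u + 1, v + 1) for u, v in g.edges()])
    return out


def all_labeled_trees(n: int) -> Iterator[List[Tuple[int, int]]]:
    """Every labelled tree on vertices 1..n, decoded from Pruefer sequences.

    ``n**(n-2)`` trees; used to cross-check the skeleton list at tiny n.
    """
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(1, 2)]
        return
    for seq in itertools.product(range(1, n + 1), repeat=n - 2):
        degree = {v: 1 for v in range(1, n + 1)}
        for v in seq:
            degree[v] += 1
        edges = []
        for v in seq:
            # a vertex still due in the sequence has degree >= 2 here, so the
            # smallest degree-1 vertex is the next leaf to strip
            leaf = min(u for u in degree if degree[u] == 1)
            edges.append((leaf, v))
            degree[leaf] -= 1
            degree[v] -= 1
        last = [u for u in degree if degree[u] == 1]
        edges.append((last[0], last[1]))
        yield edges


def unrooted_key(
    n: int, edges: Sequence[Tuple[int, int]], loops: Dict[int, int]
) -> PairSeq:
    """Isomorphism key of an unrooted loop-tree: the maximum over all
    rootings of the rooted canonical sequence."""
    return max(
        canonicalize(tree_from_edges(n, edges, root, loops))
        for root in range(1, n + 1)
    )


def brute_rooted_classes(n: int, delta: int) -> Set[PairSeq]:
    """All canonical sequences of rooted loop-trees with ``n`` vertices and
    ``delta`` loops, by exhaustive construction."""
    _guard(n, delta)
    out: Set[PairSeq] = set()
    for edges in _skeletons(n):
        for root in range(1, n + 1):
            for comp in _compositions(delta, n):
                loops = dict(zip(range(1, n + 1), comp))
                out.add(canonicalize(tree_from_edges(n, edges, root, loops)))
    return out


def brute_unrooted_classes(n: int, delta: int) -> Set[PairSeq]:
    """One max-over-rootings key per unrooted isomorphism class."""
    _guard(n, delta)
    out: Set[PairSeq] = set()
    for edges in _skeletons(n):
        for comp in _compositions(delta, n):
            loops = dict(zip(range(1, n + 1), comp))
            out.add(unrooted_key(n, edges, loops))
    return out


def random_loop_tree(n: int, delta: int, seed: int) -> OrderedLoopTree:
    """A deterministic pseudo-random ordered loop-tree.

    Uniform random Pruefer skeleton, uniform root, loops thrown uniformly
    over vertices, children shuffled.  Same ``(n, delta, seed)`` -> same
    tree.
    """
    rng = random.Random(seed * 1000003 + n * 1009 + delta)
    if n == 1:
        base = RootedLoopTree(n=1, root=1, parent={}, loops={1: delta})
        return OrderedLoopTree(base=base, children_order={1: ()})
    if n == 2:
        edges = [(1, 2)]
    else:
        seq = [rng.randint(1, n) for _ in range(n - 2)]
        g = nx.from_prufer_sequence([v - 1 for v in seq])
        edges = [(u + 1, v + 1) for u, v in g.edges()]
    loops: Dict[int, int] = {v: 0 for v in range(1, n + 1)}
    for _ in range(delta):
        loops[rng.randint(1, n)] += 1
    base = tree_from_edges(n, edges, rng.randint(1, n), loops)
    order: Dict[int, Tuple[int, ...]] = {}
    for v, kids in base.children_map().items():
        rng.shuffle(kids)
        order[v] = tuple(kids)
    return OrderedLoopTree(base=base, children_order=order)
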