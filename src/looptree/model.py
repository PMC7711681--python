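"""Domain types and basic orderings for tree-skeleton graphs with self-loops.

The objects of study are connected multigraphs whose skeleton (the simple
graph left after removing self-loops) is a tree: ``n`` vertices, ``n - 1``
tree edges, and ``delta`` self-loops distributed over the vertices.  Such a
graph has cycle rank exactly ``delta``.  Rooting the skeleton and fixing a
left-to-right order on every vertex's children turns the graph into an
*ordered loop-tree*, which admits a sequence encoding (see
:mod:`looptree.seqrep`).

This module provides the shared vocabulary: the ``(vertices, loops)`` size
pair, rooted and ordered loop-trees, the sibling-depth-first (SDFS) vertex
ordering, lexicographic comparison of pair sequences, and the census report
container used by the polymer application.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, NamedTuple, Tuple

__all__ = [
    "SizePair",
    "PairSeq",
    "RootedLoopTree",
    "OrderedLoopTree",
    "CensusReport",
    "sdfs_order",
    "lex_compare",
]


class SizePair(NamedTuple):
    """Size of a (sub)graph: vertex count and total self-loop count.

    Being a tuple subclass, a ``SizePair`` compares and hashes exactly like
    the plain ``(n_vertices, n_loops)`` tuples used throughout the
    enumeration hot paths.
    """

    n_vertices: int
    n_loops: int


#: A pair sequence: the sequence encoding of an ordered loop-tree and the
#: currency of the whole enumeration.  Entries are ``(a, b)`` int pairs with
#: ``a >= 1`` and ``b >= 0``; plain tuples are accepted everywhere.
PairSeq = Tuple[Tuple[int, int], ...]


def lex_compare(a: PairSeq, b: PairSeq) -> int:
    """Compare two pair sequences lexicographically.

    Returns -1, 0 or 1.  Entries are compared entrywise (vertex count first,
    then loop count) and a proper prefix is smaller than any extension --
    which is exactly Python's tuple ordering, so this is a documented thin
    wrapper kept for API clarity.
    """
    a = tuple(a)
    b = tuple(b)
    if a < b:
        return -1
    if a > b:
        return 1
    return 0


@dataclass
class RootedLoopTree:
    """A rooted tree skeleton with a self-loop count on every vertex.

    Vertices are arbitrary hashable ids (the enumeration uses ``1..n``).
    ``parent`` maps every non-root vertex to its parent; ``loops`` maps every
    vertex to its nonnegative self-loop count.
    """

    n: int
    root: int
    parent: Dict[int, int]
    loops: Dict[int, int]

    @property
    def delta(self) -> int:
        """Total number of self-loops."""
        return sum(self.loops.values())

    def vertices(self) -> List[int]:
        return [self.root] + list(self.parent)

    def children_map(self) -> Dict[int, List[int]]:
        """Children of every vertex, in arbitrary (insertion) order."""
        ch: Dict[int, List[int]] = {v: [] for v in self.vertices()}
        for v, p in self.parent.items():
            ch[p].append(v)
        return ch

    def validate(self) -> None:
        """Check the tree invariants; raise ``ValueError`` on violation."""
        verts = self.vertices()
        if len(verts) != self.n or len(set(verts)) != self.n:
            raise ValueError("parent map does not define n distinct vertices")
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for v in verts:
            if self.loops.get(v, 0) < 0:
                raise ValueError(f"negative loop count on vertex {v}")
        # every vertex must reach the root without cycles
        for v in self.parent:
            seen = {v}
            while v != self.root:
                v = self.parent[v]
                if v in seen:
                    raise ValueError("cycle in parent links")
                seen.add(v)


@dataclass
class OrderedLoopTree:
    """A :class:`RootedLoopTree` plus a left-to-right order on children."""

    base: RootedLoopTree
    children_order: Dict[int, Tuple[int, ...]] = field(default_factory=dict)

    def children(self, v: int) -> Tuple[int, ...]:
        return self.children_order.get(v, ())

    def validate(self) -> None:
        self.base.validate()
        actual = self.base.children_map()
        for v in self.base.vertices():
            if sorted(self.children(v)) != sorted(actual[v]):
                raise ValueError(
                    f"children_order[{v!r}] is not a permutation of the children"
                )


def sdfs_order(tree: OrderedLoopTree) -> List[int]:
    """Vertices of ``tree`` in sibling-depth-first (SDFS) order.

    The root comes first; the children of each vertex appear consecutively in
    their left-to-right order; and the descendant block of each vertex is
    contiguous, directly after the sibling blocks that precede it.
    Concretely the order is ``root`` followed by ``block(root)`` where
    ``block(v) = children(v) ++ block(c1) ++ block(c2) ++ ...``.
    """
    out = [tree.base.root]
    stack = [tree.base.root]
    while stack:
        v = stack.pop()
        kids = tree.children(v)
        out.extend(kids)
        stack.extend(reversed(kids))
    return out


@dataclass
class CensusReport:
    """Per-parameter exact counts with provenance metadata.

    ``rows`` maps a parameter tuple -- ``(n, delta)`` for vertex/loop counts
    or ``(n, rank)`` for the polymer census -- to an exact count.
    """

    mode: str  # "rooted" | "unrooted" | "polymer"
    parameters: Tuple[int, ...]
    rows: Dict[Tuple[int, int], int]

    def total(self) -> int:
        return sum(self.rows.values())

    def iter_rows(self) -> Iterator[Tuple[int, int, int]]:
        for (n, r), c in sorted(self.rows.items()):
            yield n, r, c

    def to_csv(self) -> str:
        lines = ["n,rank,count"] if self.mode == "polymer" else ["n,loops,count"]
        lines += [f"{n},{r},{c}" for n, r, c in self.iter_rows()]
        return "\n".join(lines) + "\n"

    def format_table(self) -> str:
        head = "rank" if self.mode == "polymer" else "loops"
        width = max(len(str(c)) for c in list(self.rows.values()) + [self.total()])
        lines = [f"{'n':>4} {head:>5} {'count':>{width + 2}}"]
        for n, r, c in self.iter_rows():
            lines.append(f"{n:>4} {r:>5} {c:>{width + 2}}")
        lines.append(f"{'total':>10} {self.total():>{width + 2}}")
        return "\n".join(lines)
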