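"""Isomorph-free streams of tree-skeleton loop graphs.

Rooted enumeration walks the predecessor chain from the maximum canonical
sequence down to the star, visiting ``M(n, delta)`` exactly once each in
strictly decreasing lexicographic order.

Unrooted enumeration roots every free tree at its centroid.  A tree on
``n`` vertices has either a unicentroid (every root-subtree then holds at
most ``floor((n-1)/2)`` vertices) or, for even ``n``, a bicentroid (an edge
splitting the tree into two halves of ``n/2`` vertices each):

* unicentroid classes are the canonical sequences whose root-subtree sizes
  are all ``<= floor((n-1)/2)``; they form a contiguous suffix of the
  predecessor chain, so the walk simply starts from the largest such
  sequence instead of the global maximum;
* bicentroid classes are unordered pairs of rooted halves: loop splits
  ``b1 + b2 = delta`` with ``b1 >= b2`` and canonical halves
  ``M1 in M(n/2, b1)``, ``M2 in M(n/2, b2)``, with ``M1 >= M2`` when
  ``b1 = b2`` so each unordered pair appears once.  The two half roots are
  joined by an edge.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, NamedTuple, Optional, Tuple

from .canonical import is_canonical, max_sequence, min_sequence
from .model import PairSeq
from .predecessor import predecessor

__all__ = [
    "UnrootedClass",
    "enumerate_rooted",
    "enumerate_unrooted",
    "count",
    "unicentroid_start",
]


class UnrootedClass(NamedTuple):
    """One isomorphism class from the unrooted enumeration.

    ``kind`` is ``"unicentroid"`` (``seq`` is the centroid-rooted canonical
    sequence) or ``"bicentroid"`` (``halves`` carries the two rooted halves
    as ``(half_n, half_loops, half_sequence)``, joined root-to-root).
    """

    kind: str
    n: int
    delta: int
    seq: Optional[PairSeq] = None
    halves: Optional[Tuple[Tuple[int, int, PairSeq], Tuple[int, int, PairSeq]]] = None


def enumerate_rooted(n: int, delta: int) -> Iterator[PairSeq]:
    """All canonical sequences of rooted graphs with ``n`` vertices and
    ``delta`` self-loops, in strictly decreasing lexicographic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        yield ()
        return
    m: Optional[PairSeq] = max_sequence(n, delta)
    while m is not None:
        yield m
        m = predecessor(m, n, delta)


def unicentroid_start(n: int, delta: int) -> PairSeq:
    """Largest canonical sequence whose root-subtrees all have at most
    ``floor((n-1)/2)`` vertices -- the head of the unicentroid chain."""
    m = (n - 1) // 2
    if n % 2 == 1:
        head: Tuple[Tuple[int, int], ...] = ((m, delta), (m, 0))
    else:
        head = ((m, delta), (m, 0), (1, 0))
    return head + max_sequence(m, delta) + max_sequence(m, 0)


def _unicentroid_sequences(n: int, delta: int) -> Iterator[PairSeq]:
    if n < 3:
        return
    m: Optional[PairSeq] = unicentroid_start(n, delta)
    assert m is not None and is_canonical(m, n, delta)
    while m is not None:
        yield m
        m = predecessor(m, n, delta)


def _loop_splits(delta: int) -> Iterator[Tuple[int, int]]:
    """(b1, b2) with b1 + b2 = delta, b1 >= b2, in decreasing b1 order."""
    for b1 in range(delta, (delta - 1) // 2, -1):
        yield b1, delta - b1


def enumerate_unrooted(n: int, delta: int) -> Iterator[UnrootedClass]:
    """One representative per unrooted isomorphism class of graphs with a
    tree skeleton, ``n`` vertices, ``delta`` self-loops and no multi-edges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        yield UnrootedClass("unicentroid", n, delta, seq=())
        return
    for seq in _unicentroid_sequences(n, delta):
        yield UnrootedClass("unicentroid", n, delta, seq=seq)
    if n % 2 == 0:
        h = n // 2
        for b1, b2 in _loop_splits(delta):
            halves1 = list(enumerate_rooted(h, b1))
            halves2 = halves1 if b1 == b2 else list(enumerate_rooted(h, b2))
            for i, m1 in enumerate(halves1):
                second = halves2[i:] if b1 == b2 else halves2
                for m2 in second:
                    yield UnrootedClass(
                        "bicentroid", n, delta,
                        halves=((h, b1, m1), (h, b2, m2)),
                    )


def _bicentroid_count(n: int, delta: int) -> int:
    """Number of bicentroid classes, from the lengths of the rooted half
    chains (the halves are still produced by the predecessor walk)."""
    if n % 2 == 1:
        return 0
    h = n // 2
    sizes: Dict[int, int] = {}
    total = 0
    for b1, b2 in _loop_splits(delta):
        for b in {b1, b2}:
            if b not in sizes:
                sizes[b] = sum(1 for _ in enumerate_rooted(h, b))
        if b1 == b2:
            total += sizes[b1] * (sizes[b1] + 1) // 2
        else:
            total += sizes[b1] * sizes[b2]
    return total


def count(n: int, delta: int, mode: str = "unrooted") -> int:
    """Exact number of isomorphism classes, without materialising graphs."""
    if mode == "rooted":
        return sum(1 for _ in enumerate_rooted(n, delta))
    if mode != "unrooted":
        raise ValueError(f"unknown mode {mode!r}")
    if n == 1:
        return 1
    uni = sum(1 for _ in _unicentroid_sequences(n, delta))
    return uni + _bicentroid_count(n, delta)
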