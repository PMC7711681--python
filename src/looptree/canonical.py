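"""Canonical representation of rooted loop-trees.

Among all child orderings of a rooted loop-tree, the sequence representation
takes a lexicographic maximum; that maximum is the *canonical
representation*, one per rooted-isomorphism class.  ``M(n, delta)`` denotes
the set of canonical sequences for ``n`` vertices and ``delta`` loops.

A sequence is canonical iff, recursively at every level with root block
``(a_1, b_1) .. (a_d, b_d)`` and root-subsequences ``M(1) .. M(d)``:

  (i)   the ``a_i`` are non-increasing;
  (ii)  ``sum b_i <= delta`` and ``b_i >= b_{i+1}`` whenever ``a_i = a_{i+1}``;
  (iii) each ``M(i)`` is canonical in ``M(a_i, b_i)`` and
        ``M(i) >= M(i+1)`` whenever ``(a_i, b_i) = (a_{i+1}, b_{i+1})``.

The extremes of ``M(n, delta)`` are closed-form: the minimum is the star
with all loops on the root, the maximum the path with all loops on the
deepest leaf.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import PairSeq, RootedLoopTree

__all__ = ["min_sequence", "max_sequence", "is_canonical", "canonicalize"]


def min_sequence(n: int, delta: int = 0) -> PairSeq:
    """Lexicographic minimum of ``M(n, delta)``: ``n - 1`` copies of (1,0).

    Encodes the star with all ``delta`` loops on the root; ``delta`` does not
    appear in the entries.  Empty for ``n = 1``.
    """
    return ((1, 0),) * (n - 1)


def max_sequence(n: int, delta: int) -> PairSeq:
    """Lexicographic maximum of ``M(n, delta)``:
    ``((n-1, delta), (n-2, delta), ..., (1, delta))``.

    Encodes the rooted path whose deepest leaf carries all ``delta`` loops.
    Empty for ``n = 1``.
    """
    return tuple((a, delta) for a in range(n - 1, 0, -1))


def is_canonical(m: PairSeq, n: int, delta: int) -> bool:
    """Whether ``m`` is the canonical representation of some rooted graph
    with ``n`` vertices and ``delta`` self-loops.

    Returns ``False`` (never raises) on inadmissible input, so it can be
    used as a filter.
    """
    if n < 1 or delta < 0 or len(m) != n - 1:
        return False
    stack: List[Tuple[int, int, int, int]] = [(0, len(m), n, delta)]
    while stack:
        lo, hi, nn, dd = stack.pop()
        if nn == 1:
            continue
        acc = 0
        d = 0
        bsum = 0
        for j in range(lo, hi):
            a, b = m[j]
            if a < 1 or b < 0:
                return False
            acc += a
            bsum += b
            d += 1
            if acc >= nn - 1:
                break
        if acc != nn - 1 or bsum > dd:
            return False
        # (i) + (ii): root block sorted by (a, b) non-increasing
        for j in range(lo, lo + d - 1):
            a1, b1 = m[j]
            a2, b2 = m[j + 1]
            if a1 < a2 or (a1 == a2 and b1 < b2):
                return False
        # slice boundaries
        bounds = []
        pos = lo + d
        for j in range(lo, lo + d):
            a = m[j][0]
            bounds.append((pos, pos + a - 1))
            pos += a - 1
        if pos != hi:
            return False
        # (iii) tie-break: equal (a, b) pairs need non-increasing subsequences
        for i in range(d - 1):
            if m[lo + i] == m[lo + i + 1]:
                s1, e1 = bounds[i]
                s2, e2 = bounds[i + 1]
                if m[s1:e1] < m[s2:e2]:
                    return False
        for j in range(lo, lo + d):
            a, b = m[j]
            s, e = bounds[j - lo]
            stack.append((s, e, a, b))
    return True


def canonicalize(tree: RootedLoopTree) -> PairSeq:
    """Canonical representation of a rooted loop-tree.

    Computed bottom-up: each vertex's children are ranked by the key
    (subtree vertex count, subtree loop count, child's canonical sequence)
    in non-increasing order, mirroring conditions (i)-(iii); the vertex's
    sequence is then the sorted size block followed by the sorted
    subsequences.  Runs on an explicit stack.
    """
    kids = tree.children_map()
    canon: Dict[int, PairSeq] = {}
    size: Dict[int, Tuple[int, int]] = {}
    stack: List[Tuple[int, bool]] = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        if not done:
            stack.append((v, True))
            for c in kids[v]:
                stack.append((c, False))
            continue
        keys = sorted(
            ((size[c][0], size[c][1], canon[c]) for c in kids[v]),
            reverse=True,
        )
        seq: List[Tuple[int, int]] = [(a, b) for a, b, _ in keys]
        for _a, _b, sub in keys:
            seq.extend(sub)
        canon[v] = tuple(seq)
        size[v] = (
            1 + sum(size[c][0] for c in kids[v]),
            tree.loops.get(v, 0) + sum(size[c][1] for c in kids[v]),
        )
    return canon[tree.root]
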