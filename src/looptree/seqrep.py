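"""Sequence representation of ordered loop-trees.

An ordered loop-tree ``K`` with ``n`` vertices indexed in SDFS order is
encoded by the sequence

    SR(K) = (s(K(2)), s(K(3)), ..., s(K(n)))

where ``K(i)`` is the subtree (with its loops) hanging at the i-th SDFS
vertex and ``s`` is the (vertex count, loop count) size pair.  The SDFS
block layout makes SR recursive: with root degree ``d`` and root-subtrees
``K1..Kd`` left to right,

    SR(K) = (s(K1), ..., s(Kd)) + SR(K1) + ... + SR(Kd).

A length-``n-1`` pair sequence arising this way from *some* ordered graph
with ``n`` vertices and ``delta`` loops is called ``(n, delta)``-admissible;
admissibility is a prefix-sum recursion and the ordered graph is uniquely
reconstructible from an admissible sequence in linear time.

All recursions here run on explicit stacks, so path-shaped inputs as deep as
``n = 10**5`` are fine.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .model import OrderedLoopTree, PairSeq, RootedLoopTree, sdfs_order

__all__ = [
    "SequenceError",
    "compute_sr",
    "root_degree",
    "decompose",
    "is_admissible",
    "build_graph",
]


class SequenceError(ValueError):
    """Raised for sequences that are not decomposable / not admissible."""


def compute_sr(tree: OrderedLoopTree) -> PairSeq:
    """Sequence representation of an ordered loop-tree.

    Returns the ``n - 1`` size pairs of the subtrees at SDFS positions
    ``2..n``; the empty tuple for a single vertex.
    """
    order = sdfs_order(tree)
    loops = tree.base.loops
    # subtree sizes via explicit post-order (SDFS order itself is not
    # child-before-parent, so it cannot be accumulated in reverse)
    size_n: Dict[int, int] = {}
    size_b: Dict[int, int] = {}
    stack: List[Tuple[int, bool]] = [(tree.base.root, False)]
    while stack:
        v, done = stack.pop()
        if done:
            sn, sb = 1, loops.get(v, 0)
            for c in tree.children(v):
                sn += size_n[c]
                sb += size_b[c]
            size_n[v], size_b[v] = sn, sb
        else:
            stack.append((v, True))
            for c in tree.children(v):
                stack.append((c, False))
    return tuple((size_n[v], size_b[v]) for v in order[1:])


def root_degree(m: PairSeq, n: int) -> int:
    """The unique ``d`` with ``a_1 + ... + a_d = n - 1``.

    Prefix sums of the ``a_i >= 1`` are strictly increasing, so at most one
    ``d`` qualifies.  Raises :class:`SequenceError` if none does.
    """
    total = n - 1
    acc = 0
    for d, (a, _b) in enumerate(m, 1):
        if a < 1:
            raise SequenceError(f"entry {d} has vertex count {a} < 1")
        acc += a
        if acc == total:
            return d
        if acc > total:
            break
    raise SequenceError("no prefix of vertex counts sums to n - 1")


def decompose(
    m: PairSeq, n: int, delta: int
) -> Tuple[int, List[Tuple[int, int]], List[PairSeq]]:
    """Split a sequence into its root block and root-subsequences.

    Returns ``(d, sizes, subsequences)`` where ``sizes`` is the first-``d``
    block ``[(a_1, b_1), ..., (a_d, b_d)]`` and ``subsequences[i]`` is the
    slice of ``a_{i+1} - 1`` entries encoding the (i+1)-th root-subtree.
    Raises :class:`SequenceError` when ``m`` does not decompose (wrong
    length, no valid prefix sum, or a slice running past the end -- the last
    cannot happen once the prefix sum matches, since slice lengths add up to
    ``len(m) - d`` exactly).
    """
    if len(m) != n - 1:
        raise SequenceError(f"sequence length {len(m)} != n - 1 = {n - 1}")
    d = root_degree(m, n)
    sizes = [tuple(p) for p in m[:d]]
    subs: List[PairSeq] = []
    pos = d
    for a, _b in sizes:
        subs.append(tuple(m[pos : pos + a - 1]))
        pos += a - 1
    return d, sizes, subs


def is_admissible(m: PairSeq, n: int, delta: int) -> bool:
    """Whether ``m`` is the SR of some ordered graph with ``n`` vertices and
    ``delta`` self-loops.

    Linear time; returns ``False`` (never raises) on malformed input.
    """
    if n < 1 or delta < 0:
        return False
    # frames are (start, end, n, delta) windows into m
    stack = [(0, len(m), n, delta)]
    while stack:
        lo, hi, nn, dd = stack.pop()
        if hi - lo != nn - 1:
            return False
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
        pos = lo + d
        for j in range(lo, lo + d):
            a, b = m[j]
            stack.append((pos, pos + a - 1, a, b))
            pos += a - 1
    return True


def build_graph(m: PairSeq, n: int, delta: int) -> OrderedLoopTree:
    """Reconstruct the unique ordered loop-tree with ``SR = m``.

    Vertices are labelled ``1..n`` in SDFS order; the root of every
    (sub)tree absorbs the loops its children's size pairs do not account
    for.  Raises :class:`SequenceError` if ``m`` is not admissible.
    """
    if not is_admissible(m, n, delta):
        raise SequenceError(f"sequence is not ({n},{delta})-admissible")
    parent: Dict[int, int] = {}
    loops: Dict[int, int] = {}
    children_order: Dict[int, Tuple[int, ...]] = {}
    next_id = 2
    # frames: (vertex id, window lo, window hi, delta of this subtree)
    stack: List[Tuple[int, int, int, int]] = [(1, 0, len(m), delta)]
    while stack:
        vid, lo, hi, dd = stack.pop()
        if lo == hi:  # single vertex
            loops[vid] = dd
            children_order[vid] = ()
            continue
        nn = hi - lo + 1
        acc = 0
        d = 0
        bsum = 0
        for j in range(lo, hi):
            a, b = m[j]
            acc += a
            bsum += b
            d += 1
            if acc == nn - 1:
                break
        loops[vid] = dd - bsum
        kid_ids = tuple(range(next_id, next_id + d))
        next_id += d
        children_order[vid] = kid_ids
        frames = []
        pos = lo + d
        for i, kid in enumerate(kid_ids):
            a, b = m[lo + i]
            parent[kid] = vid
            frames.append((kid, pos, pos + a - 1, b))
            pos += a - 1
        # SDFS ids must grow left to right *and* depth blocks must follow the
        # sibling block, which the global counter handles as long as each
        # child's frame is expanded in order; a LIFO stack needs them reversed.
        # Child ids were already assigned, so expansion order only matters for
        # the grandchildren id ranges.
        stack.extend(reversed(frames))
    base = RootedLoopTree(n=n, root=1, parent=parent, loops=loops)
    return OrderedLoopTree(base=base, children_order=children_order)


def relabel_sdfs(tree: OrderedLoopTree) -> OrderedLoopTree:
    """The same ordered loop-tree with vertices renamed ``1..n`` in SDFS order."""
    order = sdfs_order(tree)
    ren = {v: i for i, v in enumerate(order, 1)}
    base = RootedLoopTree(
        n=tree.base.n,
        root=1,
        parent={ren[v]: ren[p] for v, p in tree.base.parent.items()},
        loops={ren[v]: c for v, c in tree.base.loops.items()},
    )
    return OrderedLoopTree(
        base=base,
        children_order={
            ren[v]: tuple(ren[c] for c in kids)
            for v, kids in tree.children_order.items()
        },
    )
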