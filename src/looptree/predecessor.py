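"""Immediate lexicographic predecessor in the set of canonical sequences.

Given a canonical sequence ``M`` in ``M(n, delta)``, :func:`predecessor`
returns the canonical sequence directly below it, or ``None`` at the
minimum.  Iterating from the maximum therefore enumerates ``M(n, delta)``
exactly once each, in strictly decreasing order, in O(n) amortized time per
sequence -- no candidate is ever generated and rejected.

The case analysis, with ``d`` the root degree and ``M(i)`` the
root-subsequences (their concatenation is the tail ``M[d:]``, and a
root-subsequence is minimal iff its entries are all ``(1, 0)``):

(a) every root pair is ``(1, 0)``: ``M`` is the star, no predecessor;
(b/c) the tail is minimal but some root pair exceeds ``(1, 0)``: the root
    block is the only place to go down.  Drop at the *last* slot ``j``
    whose pair is not ``(1, 0)`` -- decrement ``b_j`` when positive,
    otherwise decrement ``a_j`` and give that slot the whole remaining
    loop budget -- then refill the rest of the block greedily (largest
    admissible vertex count first, then largest admissible loop count)
    and set every subtree to its maximum sequence;
(d) some root-subsequence is not minimal (``k`` maximal): recurse on
    ``M(k)``, copy the result across the whole run of slots whose
    ``(a, b)`` pair equals slot ``k``'s, and reset the later subtrees to
    their maxima.

The greedy block refill in (b/c) deliberately deviates from the published
four-case recipe, which keeps the vertex profile fixed whenever some
``b_i > 0`` and then has gaps (it skips, e.g., ((2,1),(1,0),(1,0),(1,1))
when stepping down from ((2,1),(2,0),(1,0),(1,0)) for n=5, one loop); the
greedy rule is pinned down by brute-force gap-freeness oracle tests.

The case-(d) recursion is implemented as an explicit descend/rebuild loop,
so recursion depth never touches the interpreter limit.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .canonical import is_canonical, max_sequence
from .model import PairSeq

__all__ = ["predecessor", "NotCanonicalError"]

_MIN_PAIR = (1, 0)


class NotCanonicalError(ValueError):
    """Input to :func:`predecessor` failed the debug-mode canonicality check."""


def _root_block(m: PairSeq, n: int) -> int:
    """Root degree: unique d with a_1 + .. + a_d = n - 1."""
    total = n - 1
    acc = 0
    d = 0
    for a, _b in m:
        acc += a
        d += 1
        if acc >= total:
            break
    return d


def _concat_max(block: List[Tuple[int, int]]) -> PairSeq:
    out: List[Tuple[int, int]] = list(block)
    for a, b in block:
        out.extend(max_sequence(a, b))
    return tuple(out)


def _block_predecessor(
    ab: List[Tuple[int, int]], delta: int
) -> Optional[PairSeq]:
    """Predecessor when every root-subsequence is minimal (cases a/b/c).

    The root block is then the only place to go down.  Drop at the *last*
    slot ``j`` whose pair is not ``(1, 0)``: decrement ``b_j`` if positive,
    else decrement ``a_j`` and hand the slot the whole remaining loop
    budget.  Refill the suffix greedily -- each further slot takes the
    largest vertex count allowed (previous slot's, capped by the remaining
    vertex budget) and then the largest loop count allowed (the remaining
    loop budget, additionally capped by the previous slot's loop count when
    the vertex counts tie).  Every subtree is set to its maximum sequence.
    Returns ``None`` when all pairs are ``(1, 0)`` (the star, case (a)).
    """
    j = 0
    for i in range(len(ab), 0, -1):
        if ab[i - 1] != _MIN_PAIR:
            j = i
            break
    if j == 0:
        return None
    a_j, b_j = ab[j - 1]
    new = list(ab[: j - 1])
    used = sum(b for _a, b in new)
    if b_j > 0:
        pair = (a_j, b_j - 1)
        v_budget = sum(a for a, _b in ab[j:])
    else:
        pair = (a_j - 1, delta - used)
        v_budget = sum(a for a, _b in ab[j - 1 :]) - (a_j - 1)
    new.append(pair)
    r_budget = delta - used - pair[1]
    prev_a, prev_b = pair
    while v_budget > 0:
        a = prev_a if prev_a <= v_budget else v_budget
        b = min(prev_b, r_budget) if a == prev_a else r_budget
        new.append((a, b))
        v_budget -= a
        r_budget -= b
        prev_a, prev_b = a, b
    return _concat_max(new)


def predecessor(
    m: PairSeq, n: int, delta: int, *, check: bool = False
) -> Optional[PairSeq]:
    """The canonical sequence immediately below ``m`` in ``M(n, delta)``,
    or ``None`` when ``m`` is the minimum (the star).

    ``check=True`` validates canonicality of input and output (debug mode);
    the enumeration loop feeds outputs back in and skips the check.
    """
    if check and not is_canonical(m, n, delta):
        raise NotCanonicalError(f"input is not canonical for ({n},{delta})")
    if n < 2:
        return None

    # descend through case-(d) frames
    frames: List[Tuple[PairSeq, int, int, int, List[Tuple[int, int]], int]] = []
    cur, cur_n, cur_delta = m, n, delta
    base: Optional[PairSeq]
    while True:
        d = _root_block(cur, cur_n)
        ab = [tuple(p) for p in cur[:d]]
        # last non-minimal entry in the tail, if any
        j = None
        for idx in range(len(cur) - 1, d - 1, -1):
            if cur[idx] != _MIN_PAIR:
                j = idx
                break
        if j is None:
            base = _block_predecessor(ab, cur_delta)
            break
        # case (d): locate the slice containing j
        k = 0
        s_k = d
        pos = d
        for i in range(1, d + 1):
            a = ab[i - 1][0]
            if pos <= j < pos + a - 1:
                k, s_k = i, pos
            pos += a - 1
        a_k, b_k = ab[k - 1]
        p = 0
        while k + p + 1 <= d and ab[k + p] == (a_k, b_k):
            p += 1
        frames.append((cur, s_k, a_k - 1, p, ab, k))
        cur, cur_n, cur_delta = cur[s_k : s_k + a_k - 1], a_k, b_k

    if base is None:
        if frames:  # a non-minimal M(k) always has a predecessor
            raise AssertionError("case-(d) subsequence unexpectedly minimal")
        return None

    res = base
    for cur, s_k, slen, p, ab, k in reversed(frames):
        tail: List[Tuple[int, int]] = []
        for a, b in ab[k + p :]:
            tail.extend(max_sequence(a, b))
        res = cur[:s_k] + res * (p + 1) + tuple(tail)
    if check and not is_canonical(res, n, delta):
        raise NotCanonicalError("computed predecessor is not canonical")
    return res
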