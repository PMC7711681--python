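"""Sequence representation: SR, decomposition, admissibility, reconstruction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from looptree.model import OrderedLoopTree, RootedLoopTree
from looptree.oracle import random_loop_tree
from looptree.seqrep import (
    SequenceError,
    build_graph,
    compute_sr,
    decompose,
    is_admissible,
    relabel_sdfs,
)


class TestComputeSr:
    def test_worked_example_round_trip(self, fig4_sr):
        # the printed 11-vertex/3-loop sequence reconstructs to an ordered
        # graph whose SR is the same sequence
        k = build_graph(fig4_sr, 11, 3)
        assert compute_sr(k) == fig4_sr
        assert k.base.n == 11 and k.base.delta == 3

    def test_single_vertex_is_empty(self):
        t = OrderedLoopTree(
            base=RootedLoopTree(n=1, root=1, parent={}, loops={1: 4}),
            children_order={1: ()},
        )
        assert compute_sr(t) == ()

    def test_two_vertices_child_loop(self):
        base = RootedLoopTree(n=2, root=1, parent={2: 1}, loops={1: 0, 2: 1})
        t = OrderedLoopTree(base=base, children_order={1: (2,), 2: ()})
        assert compute_sr(t) == ((1, 1),)


class TestDecompose:
    def test_worked_example(self, fig4_sr):
        d, sizes, subs = decompose(fig4_sr, 11, 3)
        assert d == 3
        assert sizes == [(4, 1), (2, 0), (4, 2)]
        assert subs[0] == ((1, 0), (1, 1), (1, 0))
        assert subs[1] == ((1, 0),)
        assert subs[2] == ((2, 0), (1, 1), (1, 0))

    def test_star(self):
        d, sizes, subs = decompose(((1, 0), (1, 0)), 3, 0)
        assert d == 2 and subs == [(), ()]

    def test_not_decomposable(self):
        with pytest.raises(SequenceError):
            decompose(((2, 0),), 3, 0)  # wrong length
        with pytest.raises(SequenceError):
            decompose(((3, 0), (1, 0)), 3, 0)  # no prefix sums to n-1


class TestAdmissibility:
    def test_examples(self, fig4_sr):
        assert is_admissible(fig4_sr, 11, 3)
        assert is_admissible((), 1, 5)
        assert is_admissible(((1, 0), (2, 0), (1, 0)), 4, 0)

    def test_rejects(self):
        assert not is_admissible(((1, 0),), 3, 0)  # wrong length
        assert not is_admissible(((2, 0), (2, 0), (1, 0)), 4, 0)  # bad prefix sum
        assert not is_admissible(((1, 2), (1, 2)), 3, 3)  # loop budget exceeded
        assert not is_admissible(((0, 0), (2, 0)), 3, 0)  # malformed entry

    def test_sr_is_always_admissible(self):
        for seed in range(30):
            t = random_loop_tree(1 + seed % 9, seed % 4, seed)
            assert is_admissible(compute_sr(t), t.base.n, t.base.delta)


class TestBuildGraph:
    def test_single_vertex_absorbs_loops(self):
        t = build_graph((), 1, 3)
        assert t.base.loops == {1: 3}

    def test_deep_path_loops_on_leaf(self):
        t = build_graph(((2, 2), (1, 2)), 3, 2)
        assert t.base.loops == {1: 0, 2: 0, 3: 2}
        assert t.base.parent == {2: 1, 3: 2}

    def test_inadmissible_raises(self):
        with pytest.raises(SequenceError):
            build_graph(((2, 0),), 3, 0)

    def test_loop_total_and_tree_shape(self):
        m = ((4, 2), (2, 1), (1, 0), (2, 0), (1, 1), (1, 0), (1, 0))
        n, delta = 8, 3
        assert is_admissible(m, n, delta)
        t = build_graph(m, n, delta)
        assert t.base.delta == delta
        assert len(t.base.parent) == n - 1  # connected: all reach the root
        t.base.validate()

    def test_deep_recursion_path(self):
        # path of 20,000 vertices: explicit stacks, no recursion limit issues
        n = 20_000
        m = tuple((n - 1 - i, 5) for i in range(n - 1))
        t = build_graph(m, n, 5)
        assert compute_sr(t) == m


@given(st.integers(1, 10), st.integers(0, 4), st.integers(0, 10_000))
def test_round_trip_random_trees(n, delta, seed):
    t = random_loop_tree(n, delta, seed)
    m = compute_sr(t)
    rebuilt = build_graph(m, n, delta)
    assert rebuilt == relabel_sdfs(t)


def test_round_trip_thousand_fixtures():
    for seed in range(1000):
        n = 1 + (seed * 7919) % 12
        delta = (seed * 104729) % 5
        t = random_loop_tree(n, delta, seed)
        m = compute_sr(t)
        assert build_graph(m, n, delta) == relabel_sdfs(t)
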