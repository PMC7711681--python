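"""Canonical sequences: extremes, canonicality test, canonicalizer."""

import itertools

import networkx as nx
import pytest

from conftest import brute_max_sr
from looptree.canonical import canonicalize, is_canonical, max_sequence, min_sequence
from looptree.model import RootedLoopTree
from looptree.oracle import brute_rooted_classes, random_loop_tree
from looptree.seqrep import build_graph, compute_sr


class TestExtremes:
    @pytest.mark.parametrize(
        "n,delta,expect",
        [(4, 2, ((1, 0), (1, 0), (1, 0))), (1, 5, ()), (2, 0, ((1, 0),))],
    )
    def test_min_sequence(self, n, delta, expect):
        assert min_sequence(n, delta) == expect

    @pytest.mark.parametrize(
        "n,delta,expect",
        [(4, 2, ((3, 2), (2, 2), (1, 2))), (1, 0, ()), (3, 1, ((2, 1), (1, 1)))],
    )
    def test_max_sequence(self, n, delta, expect):
        assert max_sequence(n, delta) == expect

    def test_max_is_rooted_path_with_loops_on_leaf(self):
        t = build_graph(max_sequence(5, 3), 5, 3)
        assert t.base.parent == {2: 1, 3: 2, 4: 3, 5: 4}
        assert t.base.loops == {1: 0, 2: 0, 3: 0, 4: 0, 5: 3}

    def test_extremes_bound_every_canonical_sequence(self):
        for n in range(1, 7):
            for delta in range(0, 3):
                for m in brute_rooted_classes(n, delta):
                    assert min_sequence(n, delta) <= m <= max_sequence(n, delta)


class TestIsCanonical:
    def test_max_sequences_are_canonical(self):
        for n in range(1, 9):
            for delta in range(0, 4):
                assert is_canonical(max_sequence(n, delta), n, delta)
                assert is_canonical(min_sequence(n, delta), n, delta)

    def test_violations(self):
        # admissible but children sizes increase left to right
        assert not is_canonical(((1, 0), (2, 0), (1, 0)), 4, 0)
        # equal sizes but loop counts increase
        assert not is_canonical(((1, 0), (1, 1)), 3, 1)
        # inadmissible input is simply non-canonical, not an error
        assert not is_canonical(((5, 0),), 3, 0)
        assert not is_canonical(((1, 2), (1, 2)), 3, 3)

    def test_subsequence_tie_break(self):
        # two (2,0) subtrees must come with non-increasing subsequences;
        # both orders are admissible but only one is canonical
        good = ((2, 1), (2, 1), (1, 1), (1, 0))
        bad = ((2, 1), (2, 1), (1, 0), (1, 1))
        assert is_canonical(good, 5, 2)
        assert not is_canonical(bad, 5, 2)

    def test_matches_brute_force_maximum_definition(self):
        # canonical <=> equal to the max SR over all orderings of its graph
        for n in range(2, 6):
            for delta in range(0, 3):
                for m in brute_rooted_classes(n, delta):
                    assert is_canonical(m, n, delta)


class TestCanonicalize:
    def test_single_vertex(self):
        t = RootedLoopTree(n=1, root=1, parent={}, loops={1: 3})
        assert canonicalize(t) == ()

    def test_center_rooted_path_with_leaf_loop(self):
        t = RootedLoopTree(n=3, root=1, parent={2: 1, 3: 1}, loops={1: 0, 2: 1, 3: 0})
        assert canonicalize(t) == ((1, 1), (1, 0))

    def test_worked_example_sequence_is_canonical(self, fig4_sr):
        k = build_graph(fig4_sr, 11, 3)
        m = canonicalize(k.base)
        assert is_canonical(m, 11, 3)
        assert m >= fig4_sr
        # the canonical representative reconstructs and round-trips
        assert compute_sr(build_graph(m, 11, 3)) == m

    def test_equals_brute_force_max_over_orderings(self):
        for seed in range(40):
            n = 2 + seed % 6  # up to 7 vertices
            t = random_loop_tree(n, seed % 4, seed)
            assert canonicalize(t.base) == brute_max_sr(t)

    def test_invariant_under_child_reordering(self):
        t = random_loop_tree(8, 3, seed=11)
        ref = canonicalize(t.base)
        kids = t.base.children_map()
        some = [v for v in t.base.vertices() if len(kids[v]) >= 2]
        for v in some:
            perm = dict(t.children_order)
            perm[v] = tuple(reversed(perm[v]))
            # the base tree is unchanged; ordering does not enter canonicalize
            assert canonicalize(t.base) == ref


def _nx_rooted(tree: RootedLoopTree) -> nx.Graph:
    g = nx.Graph()
    for v in tree.vertices():
        g.add_node(v, loops=tree.loops.get(v, 0), is_root=v == tree.root)
    for v, p in tree.parent.items():
        g.add_edge(v, p)
    return g


def test_canonicalize_separates_rooted_isomorphism_classes():
    """Equal canonical sequence <=> rooted-isomorphic (networkx cross-check)."""
    trees = [random_loop_tree(2 + s % 5, s % 3, s).base for s in range(24)]
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["loops", "is_root"], [0, False]
    )
    for t1, t2 in itertools.combinations(trees, 2):
        if (t1.n, t1.delta) != (t2.n, t2.delta):
            continue
        same_seq = canonicalize(t1) == canonicalize(t2)
        same_iso = nx.is_isomorphic(_nx_rooted(t1), _nx_rooted(t2), node_match=nm)
        assert same_seq == same_iso
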