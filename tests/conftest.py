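import itertools

import pytest
from hypothesis import HealthCheck, settings

from looptree.io import realize
from looptree.model import OrderedLoopTree, PairSeq
from looptree.oracle import unrooted_key
from looptree.seqrep import compute_sr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: SR of the worked 11-vertex, 3-loop ordered graph (root degree 3; the
#: three root-subtrees have sizes (4,1), (2,0) and (4,2)).
FIG4_SR: PairSeq = (
    (4, 1), (2, 0), (4, 2), (1, 0), (1, 1), (1, 0), (1, 0), (2, 0), (1, 1), (1, 0),
)


@pytest.fixture
def fig4_sr() -> PairSeq:
    return FIG4_SR


def all_orderings(tree: OrderedLoopTree):
    """Every ordered version of a rooted loop-tree (brute force)."""
    base = tree.base
    kids = base.children_map()
    verts = base.vertices()
    per_vertex = [list(itertools.permutations(kids[v])) for v in verts]
    for combo in itertools.product(*per_vertex):
        yield OrderedLoopTree(base=base, children_order=dict(zip(verts, combo)))


def brute_max_sr(tree: OrderedLoopTree) -> PairSeq:
    """Lexicographic maximum of SR over all child orderings (oracle)."""
    return max(compute_sr(t) for t in all_orderings(tree))


def unrooted_item_key(item) -> PairSeq:
    """Rooting-independent key of an enumeration item, via the oracle's
    max-over-rootings rule (shares no logic with centroid rooting)."""
    n, _delta, edges, loops = realize(item)
    return unrooted_key(n, edges, loops)
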