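"""Graph writers and parsers: plain edge-list text and Graphviz DOT.

Edge-list format: a header line ``# n=<n> loops=<delta> mode=<mode>``,
then one ``u v`` line per skeleton edge with ``u < v``, then one ``v v``
line per self-loop.  Vertices are numbered 1..n in SDFS order; bicentroid
composites put the first half at 1..n/2, the second at n/2+1..n, and
include the joining edge.  Output is bit-stable for a fixed graph.
"""

from __future__ import annotations

from typing import Dict, List, TextIO, Tuple

from .enumerator import UnrootedClass
from .model import OrderedLoopTree
from .seqrep import build_graph

__all__ = [
    "realize",
    "write_edgelist",
    "write_dot",
    "parse_edgelist",
]


def realize(
    item: "UnrootedClass | OrderedLoopTree",
) -> Tuple[int, int, List[Tuple[int, int]], Dict[int, int]]:
    """Flatten a graph-like object to ``(n, delta, skeleton_edges, loops)``.

    Accepts an :class:`OrderedLoopTree` (vertices assumed 1..n) or an
    unrooted enumeration item (bicentroid halves get joined root-to-root).
    """
    if isinstance(item, OrderedLoopTree):
        base = item.base
        edges = sorted(tuple(sorted((p, v))) for v, p in base.parent.items())
        return base.n, base.delta, edges, dict(base.loops)
    if item.kind == "unicentroid":
        return realize(build_graph(item.seq, item.n, item.delta))
    (h1, b1, m1), (h2, b2, m2) = item.halves
    t1 = build_graph(m1, h1, b1).base
    t2 = build_graph(m2, h2, b2).base
    edges = [tuple(sorted((p, v))) for v, p in t1.parent.items()]
    edges += [tuple(sorted((p + h1, v + h1))) for v, p in t2.parent.items()]
    edges.append((1, 1 + h1))
    loops = dict(t1.loops)
    loops.update({v + h1: c for v, c in t2.loops.items()})
    return item.n, item.delta, sorted(edges), loops


def write_edgelist(item, sink: TextIO, mode: str = "unrooted") -> None:
    """Write one graph in the edge-list text format."""
    n, delta, edges, loops = realize(item)
    sink.write(f"# n={n} loops={delta} mode={mode}\n")
    for u, v in edges:
        sink.write(f"{u} {v}\n")
    for v in sorted(loops):
        for _ in range(loops[v]):
            sink.write(f"{v} {v}\n")


def parse_edgelist(
    text: str,
) -> Tuple[int, int, List[Tuple[int, int]], Dict[int, int]]:
    """Parse the edge-list format back to ``(n, delta, edges, loops)``."""
    n = delta = None
    edges: List[Tuple[int, int]] = []
    loops: Dict[int, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = dict(
                kv.split("=") for kv in line.lstrip("# ").split() if "=" in kv
            )
            n = int(fields["n"])
            delta = int(fields["loops"])
            loops = {v: 0 for v in range(1, n + 1)}
            continue
        u, v = map(int, line.split())
        if u == v:
            loops[u] = loops.get(u, 0) + 1
        else:
            edges.append((min(u, v), max(u, v)))
    if n is None:
        raise ValueError("missing header line")
    if sum(loops.values()) != delta:
        raise ValueError("loop lines disagree with header loop count")
    return n, delta, sorted(edges), loops


def write_dot(item, sink: TextIO, name: str = "G") -> None:
    """Write one graph as an undirected Graphviz DOT graph; each self-loop
    becomes its own ``v -- v`` edge."""
    n, _delta, edges, loops = realize(item)
    sink.write(f"graph {name} {{\n")
    for v in range(1, n + 1):
        sink.write(f"  {v};\n")
    for u, v in edges:
        sink.write(f"  {u} -- {v};\n")
    for v in sorted(loops):
        for _ in range(loops[v]):
            sink.write(f"  {v} -- {v};\n")
    sink.write("}\n")
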