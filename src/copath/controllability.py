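"""Structural-controllability primitives for a single directed layer.

A linear networked system on a directed graph is structurally controllable
from a minimum set of driver nodes determined purely by the graph: split
every node u into an out-copy u+ and an in-copy v-, turn every directed
edge (u, v) into the bipartite edge (u+, v-), and compute a maximum
matching M.  Nodes whose in-copy is unmatched are the drivers, and
|drivers| = max{n - |M|, 1}.

Because maximum matchings are generally not unique, each edge of the layer
falls into one of three classes:

* critical  — present in every maximum matching (removing it shrinks the
  maximum matching);
* redundant — present in no maximum matching;
* ordinary  — present in some but not all maximum matchings.

The classification is computed without enumerating matchings, from a
single maximum matching via alternating reachability from free vertices
and strongly connected components of the matching-oriented bipartite
digraph (the characterization behind Regin-style filtering for bipartite
matching).  The result is independent of which maximum matching is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .netmodel import BipartiteView, BNode, DirectedLayer, Edge, in_copy, out_copy

__all__ = [
    "Matching",
    "ControllabilityResult",
    "EdgeClassification",
    "build_bipartite",
    "maximum_matching",
    "driver_nodes",
    "classify_edges",
]


@dataclass
class Matching:
    """A set of directed edges, no two sharing a tail or sharing a head."""

    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        tails = [u for u, _ in self.edges]
        heads = [v for _, v in self.edges]
        if len(set(tails)) != len(tails):
            raise ValueError("matching edges share a tail")
        if len(set(heads)) != len(heads):
            raise ValueError("matching edges share a head")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tails(self) -> set[str]:
        return {u for u, _ in self.edges}

    @property
    def heads(self) -> set[str]:
        return {v for _, v in self.edges}


@dataclass
class ControllabilityResult:
    """Maximum matching plus the driver nodes it implies.

    ``drivers`` are the nodes with no incoming matched edge.  When the
    matching is perfect that set is empty but one driver is still needed;
    the smallest node label is chosen and ``arbitrary`` is set.
    """

    matching: Matching
    drivers: set[str]
    n_nodes: int
    arbitrary: bool = False

    @property
    def n_drivers(self) -> int:
        return len(self.drivers)


@dataclass
class EdgeClassification:
    """Partition of a layer's edges by their role across maximum matchings."""

    critical: set[Edge] = field(default_factory=set)
    redundant: set[Edge] = field(default_factory=set)
    ordinary: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.critical & self.redundant or self.critical & self.ordinary
                or self.redundant & self.ordinary):
            raise ValueError("edge classes overlap")

    @property
    def all_edges(self) -> set[Edge]:
        return self.critical | self.redundant | self.ordinary

    def label(self, edge: Edge) -> str:
        if edge in self.critical:
            return "critical"
        if edge in self.redundant:
            return "redundant"
        if edge in self.ordinary:
            return "ordinary"
        raise KeyError(edge)


def build_bipartite(layer: DirectedLayer) -> BipartiteView:
    """Split ``layer`` into its bipartite out-copy/in-copy representation.

    Self-loops (u, u) map to (u+, u-), which is an ordinary bipartite edge
    — self-loops are matchable, consistent with the linear-dynamics origin
    of the construction (a self-loop means the node regulates itself).
    """
    return BipartiteView(
        out_copies={out_copy(u) for u in layer.nodes},
        in_copies={in_copy(v) for v in layer.nodes},
        links={(u, v): (out_copy(u), in_copy(v)) for (u, v) in layer.edges},
    )


def _bipartite_graph(layer: DirectedLayer) -> tuple[nx.Graph, list[BNode]]:
    """Undirected bipartite graph of the layer; nodes inserted in sorted
    order so downstream matching is deterministic."""
    g = nx.Graph()
    top = [out_copy(u) for u in sorted(layer.nodes)]
    g.add_nodes_from(top)
    g.add_nodes_from(in_copy(v) for v in sorted(layer.nodes))
    for (u, v) in sorted(layer.edges):
        g.add_edge(out_copy(u), in_copy(v))
    return g, top


def maximum_matching(layer: DirectedLayer) -> Matching:
    """Maximum-cardinality matching of the layer's bipartite view,
    mapped back to original edges (Hopcroft–Karp; deterministic for a
    fixed layer via sorted node insertion)."""
    if not layer.edges:
        return Matching(set())
    g, top = _bipartite_graph(layer)
    mate = nx.bipartite.hopcroft_karp_matching(g, top_nodes=top)
    edges = {
        (b[1], mate[b][1])
        for b in mate
        if b[0] == "+"  # read each matched pair once, from the out-copy side
    }
    return Matching(edges)


def driver_nodes(layer: DirectedLayer, matching: Matching) -> ControllabilityResult:
    """Driver nodes implied by a maximum matching of ``layer``.

    Drivers are the nodes that are not the head of any matched edge; a
    control signal must be injected at each.  For a perfect matching the
    formula max{n - |M|, 1} still forces one driver: the smallest node
    label is returned with ``arbitrary=True``.

    Raises ``ValueError`` if ``matching`` is not a maximum matching of the
    layer (checked by cardinality) or uses edges outside the layer.
    """
    if not matching.edges <= layer.edges:
        raise ValueError("matching contains edges not in the layer")
    expected = len(maximum_matching(layer))
    if len(matching) != expected:
        raise ValueError(
            f"matching has {len(matching)} edges; maximum is {expected}"
        )
    drivers = layer.nodes - matching.heads
    arbitrary = False
    if not drivers and layer.nodes:
        drivers = {min(layer.nodes)}
        arbitrary = True
    return ControllabilityResult(
        matching=matching,
        drivers=drivers,
        n_nodes=layer.n_nodes,
        arbitrary=arbitrary,
    )


def classify_edges(layer: DirectedLayer) -> EdgeClassification:
    """Classify every edge as critical, redundant or ordinary.

    Works from one maximum matching M.  Orient the bipartite graph:
    unmatched edges u+ -> v-, matched edges v- -> u+.  Then

    * an unmatched edge lies in some maximum matching iff it lies on an
      alternating cycle (endpoints in the same SCC) or on an even
      alternating path starting at a free vertex (its tail is reachable
      from a free out-copy, or a free in-copy is reachable from its head);
    * a matched edge lies in every maximum matching iff it lies on no such
      cycle or path.

    The classification does not depend on which maximum matching is used.
    """
    if not layer.edges:
        return EdgeClassification()
    matching = maximum_matching(layer)
    matched = matching.edges

    d = nx.DiGraph()
    d.add_nodes_from(out_copy(u) for u in sorted(layer.nodes))
    d.add_nodes_from(in_copy(v) for v in sorted(layer.nodes))
    for (u, v) in sorted(layer.edges):
        if (u, v) in matched:
            d.add_edge(in_copy(v), out_copy(u))
        else:
            d.add_edge(out_copy(u), in_copy(v))

    free_out = [out_copy(u) for u in sorted(layer.nodes - matching.tails)]
    free_in = [in_copy(v) for v in sorted(layer.nodes - matching.heads)]

    # nodes on an alternating path from a free vertex: forward reachability
    # from free out-copies, backward reachability to free in-copies
    reach_from_free: set[BNode] = set(free_out)
    for s in free_out:
        reach_from_free |= nx.descendants(d, s)
    rev = d.reverse(copy=False)
    reach_to_free: set[BNode] = set(free_in)
    for s in free_in:
        reach_to_free |= nx.descendants(rev, s)

    scc_id: dict[BNode, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(d)):
        for b in comp:
            scc_id[b] = i

    critical: set[Edge] = set()
    redundant: set[Edge] = set()
    ordinary: set[Edge] = set()
    for (u, v) in layer.edges:
        up, vm = out_copy(u), in_copy(v)
        if (u, v) in matched:
            # arc vm -> up; an alternative exists iff the arc lies on an
            # alternating cycle or even free-rooted alternating path
            alternative = (
                scc_id[up] == scc_id[vm]
                or vm in reach_from_free
                or up in reach_to_free
            )
            (ordinary if alternative else critical).add((u, v))
        else:
            # arc up -> vm; usable in some maximum matching?
            usable = (
                scc_id[up] == scc_id[vm]
                or up in reach_from_free
                or vm in reach_to_free
            )
            (ordinary if usable else redundant).add((u, v))
    return EdgeClassification(critical=critical, redundant=redundant,
                              ordinary=ordinary)
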