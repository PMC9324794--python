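"""The CoPath procedure: conserved control paths in a multilayer network.

For each layer the edges are classified (critical / redundant / ordinary),
redundant edges are dropped, and every ordinary-or-critical edge receives a
conservative weight — the number of layers in which it is ordinary or
critical.  On each layer's ordinary induced sub-network (OIN) a
maximum-cardinality matching of maximum conservative weight is computed;
adding back the layer's critical edges restores a full maximum matching
whose stem/cycle decomposition is the layer's control paths.  Across
layers, the union edge set chi and the conservative-degree index CV
quantify how consistent the control paths are.

The per-layer maximum-weight matching is an approximation: the exact
problem (choose one maximum matching per layer maximizing CV jointly)
requires enumerating maximum matchings, which is #P-hard, so each layer is
optimized independently against the shared conservative weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .controllability import (
    EdgeClassification,
    Matching,
    classify_edges,
    maximum_matching,
)
from .netmodel import (
    BipartiteView,
    DirectedLayer,
    Edge,
    MultilayerNetwork,
    in_copy,
    out_copy,
)

__all__ = [
    "OIN",
    "ControlPath",
    "CCPResult",
    "conservative_weights",
    "build_oin",
    "mwmc_matching",
    "restore_critical",
    "extract_control_paths",
    "run_copath",
]


@dataclass
class OIN:
    """Ordinary induced sub-network of one layer, as a weighted bipartite
    view.  ``cons_weight`` maps each ordinary edge to the number of layers
    in which that edge is ordinary-or-critical (a positive integer)."""

    layer_id: str
    bipartite: BipartiteView
    cons_weight: dict[Edge, int]

    def __post_init__(self) -> None:
        if set(self.bipartite.links) != set(self.cons_weight):
            raise ValueError("cons_weight does not cover exactly the OIN edges")
        for e, w in self.cons_weight.items():
            if w < 1:
                raise ValueError(f"conservative weight of {e} must be >= 1, got {w}")

    @property
    def edges(self) -> set[Edge]:
        return set(self.bipartite.links)


@dataclass
class ControlPath:
    """A stem or cycle of matched edges.

    A stem is a simple directed path rooted at a driver (a node with no
    incoming matched edge); ``nodes`` lists its K nodes, joined by K-1
    matched edges.  A cycle's node sequence closes on itself: ``nodes``
    lists each cycle node once and the edge from the last back to the
    first is implied.
    """

    nodes: list[str]
    kind: str  # "stem" | "cycle"
    root: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stem", "cycle"):
            raise ValueError(f"kind must be 'stem' or 'cycle', got {self.kind!r}")
        if self.kind == "stem":
            if self.root is None:
                self.root = self.nodes[0]
            elif self.root != self.nodes[0]:
                raise ValueError("a stem's root is its first node")
            if len(self.nodes) < 2:
                raise ValueError("a stem has at least one matched edge")
        else:
            if len(self.nodes) < 1:
                raise ValueError("empty cycle")

    @property
    def edges(self) -> list[Edge]:
        """The matched edges traversed by this path, in order."""
        es = list(zip(self.nodes, self.nodes[1:]))
        if self.kind == "cycle":
            es.append((self.nodes[-1], self.nodes[0]))
        return es

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class CCPResult:
    """Output of :func:`run_copath` on a multilayer network."""

    layer_ids: list[str]
    per_layer_matchings: dict[str, Matching]
    chi: set[Edge]
    layer_counts: dict[Edge, int]
    cv: float
    per_layer_paths: dict[str, list[ControlPath]]
    per_layer_classifications: dict[str, EdgeClassification] = field(
        default_factory=dict
    )
    warning: str | None = None

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)


def conservative_weights(
    network: MultilayerNetwork,
    classifications: Mapping[str, EdgeClassification],
) -> dict[Edge, int]:
    """Conservative weight of every edge: the number of layers in which it
    is ordinary or critical.  Edges that are redundant (or absent) in every
    layer do not appear in the returned mapping (implicit weight 0)."""
    if set(classifications) != set(network.layer_ids):
        raise ValueError(
            "classifications must cover exactly the network's layers; "
            f"got {sorted(classifications)} vs {sorted(network.layer_ids)}"
        )
    weights: dict[Edge, int] = {}
    for lid in network.layer_ids:
        cls = classifications[lid]
        for e in cls.ordinary | cls.critical:
            weights[e] = weights.get(e, 0) + 1
    return weights


def build_oin(
    layer: DirectedLayer,
    classification: EdgeClassification,
    weights: Mapping[Edge, int],
) -> OIN:
    """Restrict the layer's bipartite view to its ordinary edges, attaching
    their conservative weights."""
    ordinary = classification.ordinary
    missing = [e for e in ordinary if e not in weights]
    if missing:
        raise ValueError(
            f"layer {layer.layer_id!r}: no conservative weight for ordinary "
            f"edges {sorted(missing)[:5]}"
        )
    endpoints = {n for e in ordinary for n in e}
    view = BipartiteView(
        out_copies={out_copy(u) for u in endpoints},
        in_copies={in_copy(v) for v in endpoints},
        links={(u, v): (out_copy(u), in_copy(v)) for (u, v) in ordinary},
    )
    return OIN(
        layer_id=layer.layer_id,
        bipartite=view,
        cons_weight={e: int(weights[e]) for e in ordinary},
    )


def mwmc_matching(
    oin: OIN,
    tiebreak_weights: Mapping[Edge, float] | None = None,
) -> Matching:
    """Maximum-cardinality matching of the OIN with maximum total
    conservative weight among all maximum-cardinality matchings.

    Solved as a rectangular assignment problem: every edge's profit is
    offset by a constant exceeding the total conservative weight, so any
    extra matched edge outweighs any weight difference; dummy columns let
    tails stay unmatched.  ``tiebreak_weights`` optionally break remaining
    ties by original edge weights, scaled so they can never override a
    difference in cardinality or conservative weight (conservative weights
    are integers, so a total tie-break contribution < 1/2 is inert).
    """
    edges = sorted(oin.edges)
    if not edges:
        return Matching(set())
    tails = sorted({u for u, _ in edges})
    heads = sorted({v for _, v in edges})
    ti = {u: i for i, u in enumerate(tails)}
    hj = {v: j for j, v in enumerate(heads)}

    total_w = sum(oin.cons_weight.values())
    big = float(total_w + 1)  # cardinality dominates conservative weight

    tb = {}
    if tiebreak_weights:
        vals = [float(tiebreak_weights.get(e, 1.0)) for e in edges]
        lo, hi = min(vals), max(vals)
        if hi > lo:
            # each contribution in [0, 0.49/len(edges)] -> total < 1/2
            scale = 0.49 / (len(edges) * (hi - lo))
            tb = {e: (v - lo) * scale for e, v in zip(edges, vals)}

    nr, nc = len(tails), len(heads)
    # columns = real heads + one dummy per tail (profit 0 = stay unmatched)
    profit = np.zeros((nr, nc + nr))
    for e in edges:
        u, v = e
        profit[ti[u], hj[v]] = big + oin.cons_weight[e] + tb.get(e, 0.0)
    rows, cols = linear_sum_assignment(profit, maximize=True)
    chosen = {
        (tails[r], heads[c])
        for r, c in zip(rows, cols)
        if c < nc and (tails[r], heads[c]) in oin.edges
    }
    return Matching(chosen)


def restore_critical(
    matching: Matching, classification: EdgeClassification
) -> Matching:
    """Add the layer's critical edges back to an ordinary-edge matching.

    Critical edges belong to every maximum matching and ordinary matched
    edges extend one, so the union must itself be a valid matching; a
    tail/head clash indicates an upstream classification bug and raises
    ``RuntimeError`` rather than silently dropping edges.
    """
    overlap_ord = matching.edges & classification.redundant
    if overlap_ord:
        raise ValueError(f"matching contains redundant edges: {overlap_ord}")
    combined = matching.edges | classification.critical
    try:
        return Matching(set(combined))
    except ValueError as exc:
        raise RuntimeError(
            "critical edges conflict with the ordinary matching; "
            "this indicates an internal classification error"
        ) from exc


def extract_control_paths(
    layer: DirectedLayer, matching: Matching
) -> list[ControlPath]:
    """Decompose a matching into its stems and cycles.

    Matched edges have pairwise-distinct tails and heads, so they form a
    function from tails to heads whose graph is a disjoint union of simple
    paths (stems) and simple cycles.  Stems are rooted at nodes with no
    incoming matched edge; every matched edge lies in exactly one path.
    Output order: stems sorted by root label, then cycles sorted by their
    smallest node (each cycle rotated to start at it).
    """
    if not matching.edges <= layer.edges:
        raise ValueError("matching contains edges not in the layer")
    succ = {u: v for u, v in matching.edges}
    heads = matching.heads
    paths: list[ControlPath] = []
    visited: set[str] = set()

    for root in sorted(set(succ) - heads):
        seq = [root]
        cur = root
        while cur in succ:
            cur = succ[cur]
            seq.append(cur)
        visited.update(seq[:-1])  # all but the terminal node have out-edges used
        visited.add(seq[-1])
        paths.append(ControlPath(nodes=seq, kind="stem", root=root))

    remaining = sorted(set(succ) - visited)
    seen: set[str] = set()
    cycles: list[ControlPath] = []
    for start in remaining:
        if start in seen:
            continue
        cyc = [start]
        cur = succ[start]
        while cur != start:
            cyc.append(cur)
            cur = succ[cur]
        seen.update(cyc)
        # canonical rotation: begin at the smallest label
        k = cyc.index(min(cyc))
        cyc = cyc[k:] + cyc[:k]
        cycles.append(ControlPath(nodes=cyc, kind="cycle"))
    cycles.sort(key=lambda cp: cp.nodes[0])
    return paths + cycles


def run_copath(
    network: MultilayerNetwork,
    use_weight_tiebreak: bool = False,
) -> CCPResult:
    """Run the full conserved-control-path detection on a multilayer network.

    Per layer: classify edges, build the weighted OIN, find the
    maximum-cardinality maximum-conservative-weight matching, restore the
    critical edges, and extract control paths.  Across layers: assemble the
    union edge set chi, the per-edge layer counts and the CV index.

    With ``use_weight_tiebreak`` the layers' original edge weights break
    ties among equally conserved matchings; by default original weights do
    not enter the objective at all, so the result depends only on topology.
    """
    from .metrics import cv as cv_index

    classifications = {l.layer_id: classify_edges(l) for l in network.layers}
    weights = conservative_weights(network, classifications)

    per_layer_matchings: dict[str, Matching] = {}
    per_layer_paths: dict[str, list[ControlPath]] = {}
    for layer in network.layers:
        cls = classifications[layer.layer_id]
        oin = build_oin(layer, cls, weights)
        tb = (
            {e: layer.weight(e) for e in oin.edges} if use_weight_tiebreak else None
        )
        m_ord = mwmc_matching(oin, tiebreak_weights=tb)
        m_full = restore_critical(m_ord, cls)
        expected = len(maximum_matching(layer))
        if len(m_full) != expected:
            raise RuntimeError(
                f"layer {layer.layer_id!r}: restored matching has "
                f"{len(m_full)} edges, maximum is {expected}"
            )
        per_layer_matchings[layer.layer_id] = m_full
        per_layer_paths[layer.layer_id] = extract_control_paths(layer, m_full)

    report = cv_index([per_layer_matchings[lid] for lid in network.layer_ids])
    chi: set[Edge] = set()
    for m in per_layer_matchings.values():
        chi |= m.edges
    counts = {
        e: sum(1 for m in per_layer_matchings.values() if e in m.edges)
        for e in chi
    }
    return CCPResult(
        layer_ids=list(network.layer_ids),
        per_layer_matchings=per_layer_matchings,
        chi=chi,
        layer_counts=counts,
        cv=report.cv,
        per_layer_paths=per_layer_paths,
        per_layer_classifications=classifications,
        warning=report.warning,
    )
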