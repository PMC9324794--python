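"""Domain types for directed multilayer networks and their on-disk formats.

A multilayer network is an ordered collection of directed layers.  Node
identity across layers is by label: the same string in two layers denotes
the same entity (e.g. the same gene in two cancer-specific networks).
Interlayer couplings are carried for completeness but ignored by every
algorithm in this package, which targets multilayer networks without
cross-layer links.

On-disk formats are deliberately minimal and text-based:

* layer edge list — TSV ``tail<TAB>head[<TAB>weight]``, ``#`` comments;
* manifest — one ``layer_id: path`` per line (paths relative to the
  manifest), ``#`` comments;
* results — per-layer matching TSVs, per-layer control-path files and a
  JSON summary (see :func:`write_result`).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

__all__ = [
    "Edge",
    "DirectedLayer",
    "MultilayerNetwork",
    "BipartiteView",
    "read_layer",
    "write_layer",
    "read_multilayer",
    "write_result",
]

#: A directed edge as an ordered (tail, head) pair of node labels.
Edge = tuple[str, str]


class ParseError(ValueError):
    """A malformed line in an on-disk file; carries the 1-based line number."""


@dataclass
class DirectedLayer:
    """One layer of a multilayer network: a labeled directed graph.

    Parameters
    ----------
    layer_id:
        Short identifier, unique within a network.
    nodes:
        Node labels.  Always a superset of the edge endpoints.
    edges:
        Set of ordered ``(tail, head)`` pairs.  Self-loops are allowed.
    weights:
        Optional edge -> weight mapping; edges absent from the mapping
        have weight 1.0.  All weights must be finite.
    """

    layer_id: str
    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    weights: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v) in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(
                    f"layer {self.layer_id!r}: edge ({u!r}, {v!r}) has an "
                    "endpoint outside the node set"
                )
        for e, w in self.weights.items():
            if e not in self.edges:
                raise ValueError(
                    f"layer {self.layer_id!r}: weight given for non-edge {e!r}"
                )
            if not math.isfinite(w):
                raise ValueError(
                    f"layer {self.layer_id!r}: non-finite weight for edge {e!r}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, edge: Edge) -> float:
        """Weight of ``edge`` (1.0 if no weight was supplied)."""
        return self.weights.get(edge, 1.0)

    def copy(self, layer_id: str | None = None) -> "DirectedLayer":
        return DirectedLayer(
            layer_id=self.layer_id if layer_id is None else layer_id,
            nodes=set(self.nodes),
            edges=set(self.edges),
            weights=dict(self.weights),
        )


@dataclass
class MultilayerNetwork:
    """An ordered collection of :class:`DirectedLayer` objects.

    ``couplings`` stores interlayer links as ``(layer_id, node, layer_id,
    node)`` quadruples; they are parsed and carried but never used by the
    algorithms, which operate layer by layer.
    """

    layers: list[DirectedLayer]
    couplings: set[tuple[str, str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a multilayer network needs at least one layer")
        ids = [l.layer_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate layer_id in {ids}")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_ids(self) -> list[str]:
        return [l.layer_id for l in self.layers]

    def layer(self, layer_id: str) -> DirectedLayer:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(f"no layer {layer_id!r} in network")


#: Bipartite copy of a node: ('+', u) is the out-copy u+, ('-', v) the
#: in-copy v-.  Tuples avoid collisions with node labels containing +/-.
BNode = tuple[str, str]


def out_copy(u: str) -> BNode:
    return ("+", u)


def in_copy(v: str) -> BNode:
    return ("-", v)


@dataclass
class BipartiteView:
    """Bipartite split representation of a directed layer.

    Every node u contributes an out-copy u+ and an in-copy v-; every
    directed edge (u, v) becomes the bipartite edge (u+, v-).  ``links``
    is a bijection between original and bipartite edges.
    """

    out_copies: set[BNode]
    in_copies: set[BNode]
    links: dict[Edge, tuple[BNode, BNode]]

    def __post_init__(self) -> None:
        seen = set(self.links.values())
        if len(seen) != len(self.links):
            raise ValueError("links is not injective")
        for (u, v), (up, vm) in self.links.items():
            if up != out_copy(u) or vm != in_copy(v):
                raise ValueError(f"link for edge ({u}, {v}) is inconsistent")


# ---------------------------------------------------------------------------
# readers / writers


def read_layer(path: str | os.PathLike, layer_id: str) -> DirectedLayer:
    """Read a layer from a TSV edge list.

    Lines are ``tail<TAB>head`` or ``tail<TAB>head<TAB>weight``; blank
    lines and lines starting with ``#`` are skipped.  Extra columns beyond
    the third are tolerated (real-world deposits vary) but reported via a
    :class:`UserWarning`.  Duplicate edges collapse to one, keeping the
    last weight seen.
    """
    import warnings

    nodes: set[str] = set()
    edges: set[Edge] = set()
    weights: dict[Edge, float] = {}
    warned_extra = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected 'tail<TAB>head[<TAB>weight]', "
                    f"got {line!r}"
                )
            if len(cols) > 3 and not warned_extra:
                warnings.warn(
                    f"{path}:{lineno}: extra columns beyond the third are ignored",
                    UserWarning,
                    stacklevel=2,
                )
                warned_extra = True
            tail, head = cols[0], cols[1]
            edge = (tail, head)
            nodes.add(tail)
            nodes.add(head)
            edges.add(edge)
            if len(cols) >= 3 and cols[2] != "":
                try:
                    w = float(cols[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {cols[2]!r}"
                    ) from exc
                if not math.isfinite(w):
                    raise ParseError(f"{path}:{lineno}: non-finite weight {cols[2]!r}")
                weights[edge] = w
            else:
                weights.pop(edge, None)  # last occurrence wins, unweighted
    return DirectedLayer(layer_id=layer_id, nodes=nodes, edges=edges, weights=weights)


def write_layer(layer: DirectedLayer, path: str | os.PathLike) -> None:
    """Write a layer as a TSV edge list (weights only where non-default)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# layer {layer.layer_id}: {layer.n_nodes} nodes, "
                 f"{layer.n_edges} edges\n")
        for (u, v) in sorted(layer.edges):
            if (u, v) in layer.weights:
                fh.write(f"{u}\t{v}\t{layer.weights[(u, v)]!r}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        # isolated nodes cannot be expressed in an edge list; record them
        isolated = sorted(layer.nodes - {n for e in layer.edges for n in e})
        for n in isolated:
            fh.write(f"# isolated\t{n}\n")


def read_multilayer(manifest: str | os.PathLike) -> MultilayerNetwork:
    """Read a multilayer network from a manifest file.

    Each non-comment line of the manifest is ``layer_id: path`` (or
    ``layer_id<TAB>path``); paths are resolved relative to the manifest's
    directory and layers are loaded in manifest order.  An optional line
    ``@couplings: path`` names a 4-column TSV of interlayer links.
    """
    base = os.path.dirname(os.path.abspath(manifest))
    entries: list[tuple[str, str]] = []
    couplings_path: str | None = None
    with open(manifest, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                key, _, value = line.partition("\t")
            elif ":" in line:
                key, _, value = line.partition(":")
            else:
                raise ParseError(
                    f"{manifest}:{lineno}: expected 'layer_id: path', got {line!r}"
                )
            key, value = key.strip(), value.strip()
            if not key or not value:
                raise ParseError(f"{manifest}:{lineno}: empty layer_id or path")
            if key == "@couplings":
                couplings_path = value
            else:
                entries.append((key, value))
    ids = [k for k, _ in entries]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{manifest}: duplicate layer_id among {ids}")
    layers = [
        read_layer(os.path.join(base, p), layer_id=lid) for lid, p in entries
    ]
    couplings: set[tuple[str, str, str, str]] = set()
    if couplings_path is not None:
        with open(os.path.join(base, couplings_path), encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 4:
                    raise ParseError(
                        f"{couplings_path}:{lineno}: expected 4 columns"
                    )
                couplings.add((cols[0], cols[1], cols[2], cols[3]))
    return MultilayerNetwork(layers=layers, couplings=couplings)


def write_result(result, out_dir: str | os.PathLike) -> list[str]:
    """Write a CCP detection result to ``out_dir``.

    Emits, for every layer, ``<id>.matching.tsv`` (matched edges, one per
    line) and ``<id>.paths.txt`` (one control path per line, nodes joined
    by ``->``; cycle lines end with ``*``), plus ``summary.json`` holding
    the CV, |chi| and the per-edge layer counts.  Returns the list of file
    paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for lid in result.layer_ids:
        m = result.per_layer_matchings[lid]
        mpath = os.path.join(out_dir, f"{lid}.matching.tsv")
        with open(mpath, "w", encoding="utf-8") as fh:
            for (u, v) in sorted(m.edges):
                fh.write(f"{u}\t{v}\n")
        written.append(mpath)
        ppath = os.path.join(out_dir, f"{lid}.paths.txt")
        with open(ppath, "w", encoding="utf-8") as fh:
            for cp in result.per_layer_paths[lid]:
                suffix = "*" if cp.kind == "cycle" else ""
                fh.write("->".join(cp.nodes) + suffix + "\n")
        written.append(ppath)
    summary = {
        "cv": result.cv,
        "chi_size": len(result.chi),
        "n_layers": len(result.layer_ids),
        "layer_ids": result.layer_ids,
        "empty_chi": len(result.chi) == 0,
        "layer_counts": {f"{u}\t{v}": c
                         for (u, v), c in sorted(result.layer_counts.items())},
    }
    spath = os.path.join(out_dir, "summary.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(spath)
    return written
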