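"""Seeded generators of synthetic multilayer networks and perturbations.

The generators are the test bed for the simulation study of conserved
control paths: scale-free layers from the *static model* (node i carries
weight i^(-alpha), alpha = 1/(gamma-1); edge endpoints are sampled
proportionally to those weights, giving degree exponent gamma) or uniform
Erdos-Renyi layers, assembled into a multilayer network that shares a
controlled pool of common edges, with optional node-label divergence
between layers, Gaussian edge-weight noise and degree-preserving
edge-crossing perturbations.

All generators are pure functions of (spec, seed): the same inputs always
produce the same network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netmodel import DirectedLayer, Edge, MultilayerNetwork

__all__ = [
    "SyntheticSpec",
    "generate_layer",
    "generate_multilayer",
    "add_weight_noise",
    "cross_edges",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic multilayer world.

    Defaults are the desk-scale simulation conditions: 10 scale-free
    layers of n=1000 nodes and m=1500 edges with degree exponent 2.5,
    independent layers (no enforced common edges), identical node sets and
    noise-free unit weights.
    """

    n_layers: int = 10
    n_nodes: int = 1000
    n_edges: int = 1500
    model: str = "SF"  # "SF" (static model) | "ER"
    gamma: float = 2.5  # target degree exponent of the SF static model
    p_common: float = 0.0  # proportion of candidate common edges per layer
    preserve_frac: float = 0.5  # fraction of common edges enforced in all layers
    node_diff_ratio: float = 0.0  # fraction of relabeled nodes per layer
    noise_sigma: float = 0.0  # sd of Gaussian weight noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_edges < 0 or self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for n_nodes={self.n_nodes} "
                "(no self-loops, no duplicates)"
            )
        if self.model not in ("SF", "ER"):
            raise ValueError(f"model must be 'SF' or 'ER', got {self.model!r}")
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError("p_common must be in [0, 1]")
        if not 0.0 <= self.preserve_frac <= 1.0:
            raise ValueError("preserve_frac must be in [0, 1]")
        if not 0.0 <= self.node_diff_ratio <= 1.0:
            raise ValueError("node_diff_ratio must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")


def _node_label(i: int) -> str:
    return f"n{i:06d}"


def _static_weights(n: int, gamma: float) -> np.ndarray:
    alpha = 1.0 / (gamma - 1.0)
    w = (np.arange(1, n + 1, dtype=float)) ** (-alpha)
    return w / w.sum()


def _sample_edges(
    rng: np.random.Generator,
    n: int,
    m: int,
    p: np.ndarray | None,
    forbidden: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Sample m distinct non-self-loop edges (as index pairs), endpoint
    probabilities p (None = uniform), excluding ``forbidden`` pairs."""
    out: list[tuple[int, int]] = []
    have: set[tuple[int, int]] = set() if forbidden is None else set(forbidden)
    need = m
    max_rounds = 1000
    while need > 0 and max_rounds > 0:
        batch = max(4 * need, 64)
        if p is None:
            tails = rng.integers(0, n, size=batch)
            heads = rng.integers(0, n, size=batch)
        else:
            tails = rng.choice(n, size=batch, p=p)
            heads = rng.choice(n, size=batch, p=p)
        for t, h in zip(tails, heads):
            if t == h:
                continue
            pair = (int(t), int(h))
            if pair in have:
                continue
            have.add(pair)
            out.append(pair)
            need -= 1
            if need == 0:
                break
        max_rounds -= 1
    if need > 0:
        raise RuntimeError(
            f"could not sample {m} distinct edges on {n} nodes "
            f"({m - need} found); edge count too close to saturation"
        )
    return out


def generate_layer(spec: SyntheticSpec, seed: int) -> DirectedLayer:
    """Generate one directed layer under ``spec``'s model.

    SF mode uses the static model: endpoint i is drawn with probability
    proportional to i^(-alpha), alpha = 1/(gamma-1), and tail/head draws
    repeat until ``n_edges`` distinct non-self-loop edges exist.  ER mode
    draws endpoints uniformly.  Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(seed)
    p = _static_weights(spec.n_nodes, spec.gamma) if spec.model == "SF" else None
    pairs = _sample_edges(rng, spec.n_nodes, spec.n_edges, p)
    edges = {(_node_label(t), _node_label(h)) for t, h in pairs}
    nodes = {_node_label(i) for i in range(spec.n_nodes)}
    return DirectedLayer(layer_id="L1", nodes=nodes, edges=edges)


def generate_multilayer(spec: SyntheticSpec) -> MultilayerNetwork:
    """Generate a multilayer network with a controlled common-edge pool.

    A base layer is generated first and ``floor(p_common * n_edges)`` of
    its edges become the candidate common edges.  Of those, a fraction
    ``preserve_frac`` is preserved across *all* layers — the shared pool S
    (the simulation study this generator emulates preserves 50% of the
    common edges across layers, hence the default).  Every layer is S plus
    fresh layer-specific edges (same model) topping it up to ``n_edges``.
    Before any node relabeling, every pair of layers therefore shares at
    least |S| = ``floor(preserve_frac * p_common * n_edges)`` edges; with
    ``p_common=1, preserve_frac=1`` all layers are identical.
    ``node_diff_ratio`` then replaces that fraction of each non-base
    layer's node labels (and relabels their incident edges) with labels
    unique to the layer, modeling layers whose node sets only partly
    coincide.  Weight noise (``noise_sigma``) is applied last,
    independently per layer.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, _MAX_SEED, size=3 * spec.n_layers + 1)
    p = _static_weights(spec.n_nodes, spec.gamma) if spec.model == "SF" else None
    n, m = spec.n_nodes, spec.n_edges

    base = generate_layer(spec, int(seeds[0]))
    base_pairs = sorted(
        (int(u[1:]), int(v[1:])) for (u, v) in base.edges
    )
    n_common = int(np.floor(spec.preserve_frac * spec.p_common * m))
    pool_idx = rng.choice(len(base_pairs), size=n_common, replace=False)
    pool = [base_pairs[i] for i in sorted(pool_idx)]

    layers: list[DirectedLayer] = []
    for l in range(spec.n_layers):
        lid = f"L{l + 1}"
        lrng = np.random.default_rng(int(seeds[1 + l]))
        specific = _sample_edges(lrng, n, m - n_common, p, forbidden=set(pool))
        pairs = pool + specific
        edges = {(_node_label(t), _node_label(h)) for t, h in pairs}
        nodes = {_node_label(i) for i in range(n)}
        layer = DirectedLayer(layer_id=lid, nodes=nodes, edges=edges)
        if l > 0 and spec.node_diff_ratio > 0:
            layer = _relabel_nodes(
                layer, spec.node_diff_ratio, int(seeds[1 + spec.n_layers + l]), lid
            )
        if spec.noise_sigma > 0:
            layer = add_weight_noise(
                layer, spec.noise_sigma, int(seeds[1 + 2 * spec.n_layers + l])
            )
        layers.append(layer)
    return MultilayerNetwork(layers=layers)


def _relabel_nodes(
    layer: DirectedLayer, ratio: float, seed: int, lid: str
) -> DirectedLayer:
    """Replace a fraction of node labels with fresh layer-specific labels.

    Relabeling rather than deleting keeps every layer the same size; the
    relabeled nodes (and their incident edges) simply stop coinciding with
    other layers' nodes.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(layer.nodes)
    k = int(np.floor(ratio * len(nodes)))
    chosen = rng.choice(len(nodes), size=k, replace=False)
    mapping = {nodes[i]: f"{lid}x{nodes[i]}" for i in chosen}
    new_nodes = {mapping.get(u, u) for u in layer.nodes}
    new_edges = {(mapping.get(u, u), mapping.get(v, v)) for (u, v) in layer.edges}
    new_weights = {
        (mapping.get(u, u), mapping.get(v, v)): w
        for (u, v), w in layer.weights.items()
    }
    return DirectedLayer(layer_id=layer.layer_id, nodes=new_nodes,
                         edges=new_edges, weights=new_weights)


def add_weight_noise(layer: DirectedLayer, sigma: float, seed: int) -> DirectedLayer:
    """Add N(0, sigma) noise to every edge weight; topology untouched."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return layer.copy()
    rng = np.random.default_rng(seed)
    edges = sorted(layer.edges)
    noise = rng.normal(0.0, sigma, size=len(edges))
    weights = {e: layer.weight(e) + float(x) for e, x in zip(edges, noise)}
    return DirectedLayer(
        layer_id=layer.layer_id,
        nodes=set(layer.nodes),
        edges=set(layer.edges),
        weights=weights,
    )


def cross_edges(layer: DirectedLayer, k: int, seed: int) -> DirectedLayer:
    """Perform k degree-preserving double-edge swaps.

    Each swap picks two edges (a->b, c->d) and rewires them to
    (a->d, c->b), rejecting proposals that would create a self-loop or a
    duplicate edge.  In- and out-degrees of every node, and the edge
    count, are preserved exactly.  Raises ``RuntimeError`` (reporting the
    number of completed swaps) if the swap budget cannot be met within a
    bounded number of rejections.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    edges = sorted(layer.edges)
    if k == 0:
        return layer.copy()
    if len(edges) < 2:
        raise RuntimeError("cannot swap: fewer than 2 edges (0 swaps completed)")
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    done = 0
    attempts = 0
    max_attempts = 200 * k + 1000
    while done < k and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[int(i)], edges[int(j)]
        new1, new2 = (a, d), (c, b)
        if a == d or c == b:
            continue
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[int(i)], edges[int(j)] = new1, new2
        done += 1
    if done < k:
        raise RuntimeError(
            f"edge crossing infeasible: {done} of {k} swaps completed "
            f"within {max_attempts} attempts"
        )
    # crossed edges take the default weight; original weights follow edges
    # that survived unswapped
    weights = {e: w for e, w in layer.weights.items() if e in edge_set}
    return DirectedLayer(
        layer_id=layer.layer_id,
        nodes=set(layer.nodes),
        edges=edge_set,
        weights=weights,
    )
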