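# copath

Conserved control paths in directed multilayer networks.

Many complex systems — signaling networks perturbed differently across
cancer types, social networks split by relationship type, layered
infrastructure — are best described as *multilayer* networks: the same
entities, wired differently in each layer. A linear system on a directed
network is structurally controllable from a minimum set of *driver nodes*
determined by a maximum matching: split each node u into an out-copy u⁺ and
an in-copy u⁻, map each edge (u, v) to the bipartite edge (u⁺, v⁻), and
compute a maximum matching M. Unmatched nodes are the drivers
(|drivers| = max{n − |M|, 1}), and the matched edges decompose into *stems*
and *cycles* — the control paths along which injected signals propagate.

Maximum matchings are rarely unique. `copath` finds, for each layer, the
maximum matching whose control paths are the most *conserved* across
layers, and quantifies that consistency:

- Each edge is classified **critical** (in every maximum matching),
  **redundant** (in none) or **ordinary** (in some), from a single matching
  via alternating reachability and strongly connected components — no
  enumeration.
- The **conservative weight** ŵ(e) = Σ_l 1[e ordinary-or-critical in layer l]
  counts the layers where an edge can participate in control.
- On each layer's **ordinary induced sub-network** (OIN) a
  maximum-cardinality matching of maximum total ŵ is computed; adding the
  critical edges back restores a full maximum matching.
- The **conservative degree** of the union χ of the per-layer matchings,

  CV(χ) = (1/|χ|) Σ_{e∈χ} ((1/L) Σ_l 1[e ∈ M_l])²,

  ranges from (1/L)² (pairwise-disjoint control paths) to 1 (identical
  control paths in every layer).

A seeded generator of synthetic scale-free (static-model) and Erdős–Rényi
multilayer networks with a controlled common-edge pool, node-label
divergence, Gaussian weight noise and degree-preserving edge crossings
supports simulation studies (`copath.synthetic`, `copath.experiments`).

## Worked example

```python
from copath import DirectedLayer, MultilayerNetwork, run_copath

toy = DirectedLayer(
    "l1",
    nodes={"1", "2", "3", "4", "5"},
    edges={("1", "2"), ("2", "3"), ("2", "4"), ("2", "5"), ("4", "5")},
)
chain = DirectedLayer("l3", nodes={"2", "3", "6"}, edges={("2", "3"), ("3", "6")})
net = MultilayerNetwork(layers=[toy, toy.copy("l2"), chain])
result = run_copath(net)
```

Running `python examples/three_layer_ccp.py` (this network) prints:

```
conservative weight of 2->3: 3 (ordinary-or-critical in all 3 layers)
CV = 0.5000 over |chi| = 4 union edges
  l1: matching [('1', '2'), ('2', '3'), ('4', '5')]  paths: 1->2->3, 4->5
  l2: matching [('1', '2'), ('2', '3'), ('4', '5')]  paths: 1->2->3, 4->5
  l3: matching [('2', '3'), ('3', '6')]  paths: 2->3->6
layers containing 2->3 in their matching: 3 of 3
```

The edge 2→3 is usable in every layer, so its conservative weight (3)
steers all three matchings to include it; CV = 0.5 because the chain layer
cannot share the toy layers' remaining matched edges. The other scripts in
`examples/` cover single-layer controllability and edge classification
(`toy_controllability.py`), disk round trips (`io_roundtrip.py`), the
CV-versus-layers/common-edges sweep (`synthetic_sweep.py`) and weight-noise
robustness (`noise_robustness.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the CV of three identical layers (exact), and
the mean CV of the detection over ten freshly seeded 10-layer scale-free
multilayer networks (n = 1000, m = 1500, exponent 2.5) — once with
independently generated layers and once with a 0.9 common-edge proportion —
writing one JSON object with a value per target. Runtime is well under a
minute on one CPU.

See `docs/methods.md` for the model, the algorithmic and numerical choices,
and what the synthetic generator does and does not emulate.
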