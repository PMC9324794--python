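# Methods

## Model

A directed layer G_l = (V_l, E_l) represents one relation type over a set
of labeled nodes; a multilayer network Γ = ({G_1, …, G_L}, Φ) is an ordered
collection of layers. Node identity across layers is by label equality.
Interlayer couplings Φ are parsed and stored but ignored by every
algorithm: the method addresses multilayer networks without cross-layer
links, treating each layer as an independently controllable monoplex that
shares entities with the others.

Structural controllability of a linear dynamics on a layer reduces to
bipartite matching: node u becomes an out-copy u⁺ and an in-copy u⁻, edge
(u, v) becomes (u⁺, v⁻), and a maximum matching M (no two edges sharing a
tail or a head) determines the minimum driver set — the nodes with no
incoming matched edge, of size max{n − |M|, 1}. The matched edges form a
stem-and-cycle cover: stems are simple directed paths rooted at drivers,
cycles are closed alternations; these are the control paths.

Edges partition by their role across the (generally many) maximum
matchings: critical (in all), redundant (in none), ordinary (in some).
The detection pipeline per layer is:

1. classify edges; discard redundant edges (they can never carry control);
2. assign each ordinary edge its conservative weight
   ŵ(e) = Σ_l 1[e ∈ E_l^o ∪ E_l^c], the number of layers in which the edge
   is ordinary-or-critical;
3. on the ordinary induced sub-network (OIN), find a maximum-cardinality
   matching of maximum total ŵ;
4. add the critical edges back — by the classification this cannot clash,
   and the result is a maximum matching of the full layer (asserted at run
   time, and checked against an independent maximum-matching computation).

Across layers, χ = ∪_l M_l and
CV(χ) = (1/|χ|) Σ_{e∈χ} ((1/L) Σ_l 1[e ∈ M_l])², bounded by (1/L)² and 1
for nonempty χ.

The per-layer optimization is a deliberate approximation: the exact
problem — choose one maximum matching per layer to maximize CV jointly —
would require enumerating maximum matchings, which is #P-hard. Conservative
weights couple the layers: an edge usable in many layers is preferentially
matched in each, which is what pushes the family of matchings toward
agreement.

## Algorithmic choices

**Maximum matching.** Hopcroft–Karp on the bipartite view (networkx), with
nodes and edges inserted in sorted label order so results are deterministic
for a fixed layer.

**Edge classification without enumeration.** Orient the bipartite graph by
a maximum matching M: unmatched edges u⁺ → v⁻, matched edges v⁻ → u⁺. An
edge admits an alternative maximum matching iff it lies on an alternating
cycle (its two endpoints fall in one strongly connected component) or on an
even-length alternating path starting at a free vertex (its tail is
reachable from a free out-copy, or a free in-copy is reachable from its
head). Matched edges failing both conditions are critical; unmatched edges
failing both are redundant; the rest are ordinary. The result is
independent of which maximum matching seeds it; the test suite checks exact
agreement with explicit enumeration of all maximum matchings on hundreds of
random digraphs of up to 8 nodes.

**Cardinality-before-weight matching.** The OIN matching is solved as a
rectangular linear assignment problem (scipy): each edge's profit is
ŵ(e) + B with B = (Σ ŵ) + 1, so gaining one more matched edge always beats
any redistribution of weight; one dummy zero-profit column per tail lets
tails remain unmatched. A brute-force search over all matchings pins both
the cardinality and the weight on hundreds of random weighted instances.

**Original edge weights.** By default they never enter the objective — only
conservative weights do — which is why CV is *exactly* invariant under
weight noise. An optional mode uses original weights solely to break ties
among matchings with equal cardinality and equal conservative weight: the
tie-break contributions are affinely rescaled into [0, 0.49/|E|] so their
total stays below 1/2, inert against the integer conservative weights.

**Self-loops** are matchable (u⁺ → u⁻), consistent with the linear-dynamics
origin of the construction (a self-regulating node can absorb its own
control signal).

**Tie-breaks and determinism.** All node orderings are lexicographic on
labels; perfect matchings force one driver whose identity the formula does
not determine — the smallest label is chosen and flagged `arbitrary`.
Repeated runs on the same input are identical.

**Degenerate inputs.** An all-empty family of matchings makes CV's
normalization by |χ| undefined; it is reported as 0.0 with a warning flag.
Two empty path sets have overlap 1.0 (identical emptiness). Similarity
indices are symmetric Jaccard on edge sets by default, with a gene-level
(node-set) variant and per-layer containment fractions also available,
since "fraction of overlapping edges" admits both normalizations.

## Synthetic worlds

`SyntheticSpec` defaults state the simulation conditions: L = 10 layers,
n = 1000 nodes, m = 1500 edges per layer, scale-free static-model layers
with degree exponent γ = 2.5 (node i is drawn as an endpoint with
probability ∝ i^(−α), α = 1/(γ−1)), no enforced common edges, unit weights.
n and m are desk-scale choices — large enough for heavy-tailed degrees and
sparse-regime matching structure, small enough that a ten-replicate sweep
runs in seconds per condition.

Common structure between layers is generated from a base layer: a fraction
`p_common` of its edges are the candidate common edges, and a fraction
`preserve_frac` of those (default 0.5) form a pool included in *every*
layer; each layer is then topped up with model-sampled specific edges. The
default reflects the simulation study this generator emulates, which
preserves 50% of the common edges across layers; the realized all-layer
pool at label p_common = 0.9 is therefore 0.45·m. With
`p_common = preserve_frac = 1` all layers are identical and CV = 1. With
independent layers the mean CV sits at ≈ 0.0105, essentially the (1/10)²
floor; with p_common = 0.9 it is ≈ 0.11–0.14 depending on seeds, and CV is
monotone decreasing in L and increasing in p_common — the package's
acceptance suite measures all of these.

`node_diff_ratio` *relabels* a fraction of each non-base layer's nodes
(with labels unique to the layer) rather than deleting them, keeping layer
sizes equal while shrinking the shared node set. `add_weight_noise` adds
N(0, σ) to every weight, topology untouched. `cross_edges` performs
degree-preserving double-edge swaps (a→b, c→d) ⇒ (a→d, c→b), rejecting
self-loops and duplicates, as a randomization null model.

What the generator does **not** emulate: layers of unequal node counts,
degree correlations between layers beyond the shared pool, realistic edge
weights (all base weights are 1, so σ = 25 noise fully randomizes the
optional tie-break — a stress test, not a biological noise model), or any
biological structure of real signaling networks. A green simulation test
establishes the behaviour of the method on these stated worlds only.

## Known limitations

- Per-layer optimization approximates the joint CV maximization; no bound
  on the gap is claimed.
- The assignment-based OIN matching densifies the tail×head profit matrix;
  fine at m ≈ 10⁴–10⁵ edges per layer, but very large layers would warrant
  a sparse max-cardinality/max-weight solver.
- The method requires directed layers; undirected graphs have no
  tail/head distinction and are out of scope.
- With the weight-tie-break mode on, results depend on weight scale only
  through the induced ordering of tied alternatives; under heavy noise the
  per-layer control-path edge overlap before/after stabilizes around
  0.85–0.9 at the default world — the residual tie mass among equally
  conserved matchings.
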