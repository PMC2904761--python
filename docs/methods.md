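# Methods

## The layout problem

A pathway is an undirected graph *G = (V, E)*; every node carries a
localization tag (`cytoplasm`, `nucleus`, `plasma_membrane`, ...). A
layout assigns each node a distinct point of an *h × w* integer grid,
0-based `(row, col)`. Compartments are geometric regions of the grid —
axis-aligned rectangles, ovals (standard ellipse inequality on
real-valued centers, boundary ties inside), and rectangular annuli
(outer rectangle minus the inner rectangle *including* the inner
boundary) that model membranes as frames. A node may only occupy grid
points inside the union of the compartments carrying its tag. Tags are
free strings; the bundled vocabulary is extracellular, plasma_membrane,
cytoplasm, nuclear_membrane, nucleus, mitochondria, golgi.

## Cost function

With Euclidean distance *d* in grid units,

C(P) = w_a Σ_edges F_a(d) + w_r Σ_{pairs} F_r(d) + w_e·EE + w_n·NE + pen(l)·S

* `F_a(d) = d²` (attraction, each edge once) and `F_r(d) = 1/d²`
  (repulsion, each unordered pair once). The summation convention is a
  choice — any double counting is absorbed by the weights — and is
  fixed so the default relation w_n = 2·w_e stays meaningful.
* EE counts unordered edge pairs whose straight segments intersect in
  their relative interiors; pairs sharing a graph endpoint never count
  (they are unavoidable and uninformative), collinear overlaps count
  (visually indistinguishable edges are exactly the defect the penalty
  exists for). NE counts nodes lying strictly inside foreign edges.
  All predicates use exact integer orientation arithmetic; no floating
  point geometry.
* pen(l) = α·exp(−β·l) applies once per node within one grid unit of a
  *movable* compartment's surface (surface = region cells with a
  4-neighbour outside the region, dilated by one unit). It is active
  only in the dynamic-compartment mode. Movable-only is a deliberate
  choice: the penalty's purpose is to keep nodes off geometry that may
  still change, and membrane-localized nodes necessarily sit on the
  fixed membrane frame, where a penalty would add a constant term.

Defaults: w_a = 1, w_r = 1, w_e = 10, w_n = 2·w_e, α = 20·(w + h) of
the grid, β = 0.002. Three named presets match the study pathways:
`fas` (1, 1, 10, 20), `elegans` (1, 1, 50, 100), `endothelial`
(12, 1, 50, 100). Repulsion keeps weight 1 across scales because the
grid area grows ∝ |V|, which keeps the per-node repulsive load roughly
constant under even spreading.

## Greedy search and caches

Each step moves the single node whose relocation to an admissible
vacant point decreases C the most; the search stops when no move
improves by more than 1e-9 (the convergence tolerance), or after
`max_steps` accepted moves (default 10·|V|). Ties break to the
lexicographically lowest (node id, row, col), and nodes are scanned in
ascending id order, so the search is fully deterministic; a seed only
draws the initial random layout.

A naive best-move scan costs O(|V|²·h·w) per step. The implementation
keeps three caches:

* **Repulsion field** — Σ_u F_r(d(q, P(u))) for every grid point q,
  built once from a (2h−1)×(2w−1) kernel table of F_r over all integer
  offsets (zero at the origin, so a node never interacts with its own
  position). A move updates the field with two kernel additions; the
  repulsion delta of any candidate is then three array reads.
* **Attraction tables** — per node u, the raw value Σ_{x∈N(u)}
  F_a(d(q, P(x))) for every q; the move delta is the raw value at q
  minus the raw value at P(u). A move of v only touches the tables of
  v's neighbours.
* **Crossing tables** — per node u, the EE and NE counts u would
  contribute from every candidate point. Moving v leaves v's *own*
  tables untouched (their geometry involves only other nodes),
  rebuilds the tables of N(v) (the edge (u,v) changed wholesale), and
  patches every other node's tables by the crossings gained and lost
  against v's relocated edges and v's relocated point — the standard
  case analysis of edge-edge and node-edge interactions between the
  moved node and the rest of the graph. The patches are computed as
  vectorized whole-grid predicates (int32 sign arithmetic, exact for
  grids up to 2048 a side) and aggregated per node.

Exactness, not speed, is the contract: the test suite re-derives every
cache from scratch after every accepted move on random instances and
requires bit-identical integer tables (and 1e-9-close float tables).
Running float sums are additionally recomputed from scratch every 200
accepted moves as drift insurance. The cost trace is therefore
strictly decreasing and bounded below, so the plain search terminates.

Degenerate inputs: a node with no admissible vacant point raises a
warning and is skipped ("frozen") for the pass; it is reconsidered
every subsequent pass. A move onto an occupied point is an internal
error (cache corruption), not a recoverable condition.

## Dynamic compartment update (GDC)

One search pass (up to |V| accepted moves) alternates with one
compartment update round; the round counter l drives the penalty
decay. Per movable compartment, in id order:

1. **Spread**: b_c is the mean position of the compartment's nodes;
   s_v and s_h are twice the maximum vertical / horizontal deviation
   from b_c — full-extent proxies. (Max-deviation is the package's
   reconstruction; the alternative mean-deviation statistic was
   considered and rejected as too eager to shrink around hubs.)
2. **Resize**: shrink ×0.95 iff s_v < 0.4·height AND s_h < 0.4·width;
   enlarge ×(1/0.95) iff s_v > 0.9·height OR s_h > 0.9·width; both
   dimensions scale together and sizes are clamped to [0.6, 1.5]× the
   original size. Note the dimensional pairing: vertical spread
   against height, horizontal against width.
3. **Reposition**: candidate centers are grid points within Manhattan
   distance 10 of the discretized b_c, scanned in increasing
   (distance, row, col); the first valid one wins. Valid means: every
   node of the affected tags stays inside its (updated) region, the
   compartment stays inside the grid and inside its declared
   container, and its bounding rectangle overlaps no sibling. If no
   candidate is valid, the resize is reverted and the scan repeated;
   failing that, size and position are kept. A shrink that would
   strand a node outside is thereby rejected rather than patched.

Overlap uses the corner-in-rectangle test in both directions. That
test famously misses cross-shaped overlaps (no corner of either
rectangle inside the other); it is kept as the default for fidelity to
the procedure it reproduces, and `strict_overlap=True` switches to the
exact interval-intersection test.

**Nesting.** Scenes are nested (nucleus inside cytoplasm inside the
membrane), so a blanket pairwise overlap test would always fire.
`CompartmentSpec.container` names the enclosing compartment; ancestors
are exempt from the overlap test and instead impose containment of the
bounding rectangle. The outer membrane / extracellular compartments
are immovable by convention, matching how the procedure is used.

**Convergence.** The penalty α·exp(−β·l) decays to zero, so the cost
trace converges even though compartment changes can re-enable moves.
With β = 0.002, decay below 10⁻³·α needs l > 3453; instead of looping
thousands of no-op rounds, a round in which nothing moved and nothing
resized fast-forwards l analytically to the smallest value that
re-enables any move (exact, since only l changes during no-op rounds),
or to the decay floor. After the main loop the penalty is annealed
below 10⁻³·α and a short polish pass (≤ 2·|V| moves) makes the result
a local optimum of the undecayed cost. With every compartment frozen
the whole procedure reduces bit-exactly to the plain grid search.

## Spring baseline

The continuous baseline uses the same forces (attraction d² along
edges, repulsion 1/d² between all pairs), per-node displacement capped
by a linearly cooling step (s₀ = 0.1·min(canvas), 500 iterations),
canvas clamping, and a seeded uniform start; coincident nodes are
jittered. It ignores localization constraints. Because d² vs 1/d²
equilibrates at an edge length of order |V|^¼ regardless of canvas
size, crossing comparisons rescale the final layout to the grid
bounding box (per axis) and snap nodes to distinct grid points by
minimum-total-squared-displacement assignment; edge-edge counts are
invariant under the rescale, and node-edge counts only become
meaningful on the grid.

## Synthetic pathways

The generator emulates curated signalling models: a preferential
attachment tree plus degree-biased extra edges gives exactly the
requested node and edge counts with heavy-tailed degrees (hubs such as
scaffold proteins) at average degree ≈ 2.2–2.5; localizations are
drawn from a mixture (default 5 % extracellular, 15 % membrane, 50 %
cytoplasm, 20 % nucleus, 10 % mitochondria). The default scene is a
two-unit extracellular rim, a one-unit membrane frame, the cytoplasm,
and movable nucleus and mitochondria ovals. Grid sizing follows
h = w ≈ 4·√|V|, putting (h+w)/√|V| = 8, inside the 6.5–11 band of the
curated models. What the generator does **not** emulate: biological
edge semantics (activation/inhibition, stoichiometry), directionality,
node size differences, and the strong community structure of real
pathway complexes — so passing tests demonstrate geometric and
algorithmic correctness and plausible-scale behaviour, not that real
curated maps will look as clean.

Random layouts place nodes in seeded random order, uniformly over the
still-vacant admissible points of their tag (exact uniformity over all
injective admissible assignments is intractable when regions overlap;
dead ends restart the draw).

## Problem sizes used in the checks

The self-checks run at deliberately modest sizes chosen to exercise
every code path: oracle agreement on ≥100 random instances of ≤15
nodes on ≤10×10 grids (crossings) and 50 instances of ≤12 nodes
(caches, after every accepted move); convergence and compartment
invariants on ten 50-node synthetic pathways each; the grid-vs-spring
comparison on one 84-node pathway × 10 seeds under the `fas` preset.
Under that preset the unconstrained grid layout's median crossing load
is comparable to the spring baseline's (the heavier `elegans` crossing
weights push it clearly below); the comparison is reported by the
experiment harness rather than asserted as a hard threshold, since it
is a stochastic trend that depends on the chosen weights.

## Known limitations

* Edges are straight segments; no bends, so some crossings are
  unavoidable. Node-pair swap moves and simulated annealing are not
  implemented — the search is plain greedy descent and can stall in
  local optima.
* Hypergraphs, multi-edges, self-loops and 3-D layout are out of
  scope; edge direction attributes survive IO but play no role in the
  cost.
* Compartment shapes are rectangles, ovals and rectangular frames;
  oval annuli (e.g. a curved nuclear envelope) are approximated by
  frames. Initial compartment placement is the user's job.
* The corner-test overlap check is intentionally inexact by default
  (see above).
* Exact geometry is guaranteed for grids up to 2048 on a side (int32
  sign arithmetic in the vectorized backend).
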