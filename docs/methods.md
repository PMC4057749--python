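# Methods

## The network model

A GPCR heteroreceptor network is an undirected simple graph *G = (V, E)*:
nodes are receptor protomers, each labeled with its GPCR class (F1/class A
rhodopsin-like, F2/class B secretin-like, F3/class C metabotropic
glutamate-like, or unknown), and edges are experimentally supported
heteromer interactions. Edges optionally carry the detection-method set
(coIP, BRET, FRET, SRET, TR-FRET, BiFC, PLA, FCCS), a publication count and
a controversial flag. Normalization upper-cases identifiers, drops
self-loops (homodimer detections — homomers are outside the network's
semantics, though the protomer itself is kept as a node), and merges
unordered duplicates: method sets are unioned, the publication count takes
the **maximum** of the duplicates (summing would double-count the same
literature; the union of underlying publications is unknowable from
counts), and the controversial flag is OR-ed. Isolated protomers are
first-class nodes: they stay in *N* for the density, *P(k)* and every other
metric, because a receptor with no verified partner is still part of the
surveyed population.

## Topological conventions

- *P(k)* = (nodes of degree *k*)/*N*, with *k = 0* in the support whenever
  isolated nodes exist; Σ *P(k)* = 1 to 1e−12.
- *C(n) = 2 n_l / k(k−1)*; for *k* < 2 the formula is undefined and *C(n)*
  is taken as 0, and such nodes **are** included in the global mean (the
  convention of the standard network-analysis GUIs, which produced the
  published value this package is modeled after). *C(k)* is the plain mean
  of *C(n)* over nodes of degree *k*.
- Shortest paths come from breadth-first search per source. The path-length
  histogram, mean path length and diameter are taken over **connected
  unordered pairs only**: with isolated nodes present, infinite distances
  would otherwise dominate, and the published diameter of such networks is
  plainly the maximum finite distance.
- Density *D* = 2E/N(N−1), the mean degree divided by *N* − 1.
- Relative connectivity *f* = |largest component|/*N*; edge share of a node
  subset = fraction of edges with at least one endpoint in the subset
  (equal to Σ degrees / E when the subset is an independent set).

## Model classification

Both *P(k)* and *C(k)* are fit twice: an ordinary least-squares line on the
raw (k, y) points and a least-squares line on the (log10 k, log10 y) points
(the power law y ~ k^(−γ), γ = −slope). Points with k ≤ 0 or y ≤ 0 are
excluded before the log transform; at least three must remain. R² =
1 − SS_res/SS_tot is computed on the same transformed points as each fit,
clamped to [0, 1] for reporting with the raw value retained. The log–log
convention was chosen because it is what "fit a power law by R²" means in
the network-biology GUIs this analysis style comes from; MLE (Clauset-type)
power-law estimation, CCDFs and logarithmic binning are deliberately out of
scope — the aim is fidelity to the simple-fit methodology, not optimal tail
estimation.

Decision rule (thresholds all exposed as keyword arguments):

1. **random** if the *P(k)* power-law R² does not exceed the linear R² by a
   margin δ (default 0.1);
2. otherwise **hierarchical** if the *C(k)* power-law exponent lies within
   0.3 of −1 and its R² ≥ 0.7;
3. otherwise **scale-free**.

The defaults were fixed by generator-recovery calibration logic rather than
any dataset: they must let Erdős–Rényi graphs (Poisson *P(k)*, no power
law) be called random, preferential-attachment graphs scale-free and
Ravasz-style graphs hierarchical, which the acceptance suite verifies at
≥80% over 20 seeds per model. Zero-variance (degenerate) distributions are
reported with R² = 1 but flagged and refused by the classifier, since a
constant line fits every model equally.

## Hub criteria

- **Top slice**: the ceil(0.05·N) highest-degree nodes define a realized
  degree cutoff; every node at or above the cutoff is a hub. (Phrased in
  the literature as "the top 95% of the high degree nodes"; operationally
  it is the top 5% of the degree-sorted list, extended to ties.) A uniform
  degree sequence is flagged degenerate.
- **Degree thresholds**: hubs are nodes with degree > 5 (permissive) or
  > 8 (strict); the strict set nests inside the permissive one.
- **Relative connectivity**: nodes are ordered by decreasing degree (ties:
  ascending id, for determinism — the procedure's source is silent on
  ties); induced prefix subgraphs *G_1 ⊂ G_2 ⊂ …* are grown one node at a
  time and *f_k* = |largest component of *G_k*|/k is tracked with an
  incremental union–find. Hubs interact mostly with non-hubs, so *f* falls
  while only hubs are present; the first *k* with *f_k > f_{k−1}* is the
  natural boundary and *G_{k−1}* holds the hubs. If *f* never rises (e.g.
  any complete graph) there is no boundary: the result is an empty hub set
  with an explicit status rather than a guess.
- Degree-1 nodes are reported separately as the canonical non-hubs.

## MCODE

The three-stage density search: (1) each node with at least
`degree_cutoff` = 2 neighbors is weighted by the core-clustering
coefficient — the density of the highest k-core of its closed neighborhood
— times that core's k; (2) complexes grow from the highest-weight
unassigned seed, breadth-first, admitting neighbors whose weight is within
`node_score_cutoff` = 0.2 of the seed weight; nodes join at most one
complex, so clusters are node-disjoint (re-seeding from visited nodes would
make ranks depend on traversal history); (3) candidates lacking a 2-core
are discarded, optional fluff (off by default) adds dense boundary
neighbors before the haircut iteratively strips members with fewer than two
within-cluster links. If trimming disconnects a candidate, the component
containing the seed is kept. Score = density × size; ranking is by
decreasing score, then size, then seed id. Ties everywhere resolve to
higher degree first, then ascending id.

## Synthetic generators

All generators take an integer seed and are bit-reproducible (NumPy
`default_rng`); every output is already simple and undirected.

- `gen_random(n, p)` — G(n, p) by vectorized pair sampling.
- `gen_scale_free(n, m)` — growth from a complete clique on m+1 nodes; each
  new node attaches m distinct edges degree-proportionally.
- `gen_hierarchical(levels, base_size)` — deterministic modular
  replication: the module is copied base_size−1 times per level and replica
  peripheries wire to the root hub; node count = base_size^levels and
  *C(k)* decays approximately as k^(−1).
- `gen_hetnet_like(...)` — realizes a degree-sequence skeleton exactly:
  n_isolated zeros, n_degree1 ones, an explicit top-degree list, and filler
  degrees (between 2 and one below the smallest top degree, so the
  prescribed top stays the top) distributed as evenly as the sum 2e allows.
  Realization is by stub matching; conflicting stubs (self-loops/parallels)
  are repaired by splitting random existing edges (a double-edge-swap
  move), with up to 50 restarts — heavy-tailed sequences at n ≈ 156
  occasionally defeat naive matching. Unsatisfiable constraints raise an
  error naming the violated arithmetic condition. Family labels are
  assigned at the 82/10/8% class A/B/C proportions of the curated network,
  then a seeded hill-climb swaps labels to favor intrafamily edges
  (`intrafamily_bias` scales the effort), mirroring the strong intrafamily
  dominance of real GPCR heteromers.

The default `gen_hetnet_like` parameters (156 nodes, 260 edges, 23
isolated, 57 degree-1, top degrees 17, 17, 13, 12, 11, 10, 10, 10, 10) are
the curated network's printed summary. What the surrogate emulates is the
degree skeleton and family mix — **not** the curated network's wiring: a
configuration-model graph has near-zero clustering, no biological module
structure, and its mid-range degrees are an even fill rather than the true
(unpublished) values. Consequently path lengths, clustering levels, MCODE
cluster counts and, when only the nine top degrees are pinned, even the
model-classification label of a surrogate are not expected to reproduce the
curated network's values, and no test asserts that they do; tests on
surrogates check exact constraint reproduction and procedure invariants.
With the full printed 29-entry hub-degree table pinned, threshold hub
counts (29 and 12), the top-slice cutoff (10) and the degree-1 and isolated
counts (57, 23) are degree-sequence arithmetic and reproduce exactly.

## Numerical and degenerate-input choices

- Fits require ≥ 3 usable points; fewer raise "insufficient support".
- Percentages are compared to printed values by rounding half away from
  zero at the printed precision.
- The published mean degree of 3.03 for a 156-node/260-edge network is
  inconsistent with 2E/N = 3.33; this package reports 2E/N and records the
  published figure as irreproducible from the printed counts.
- Empty graphs, edgeless graphs and single nodes raise informative errors
  in the operations whose definitions need pairs, edges or variance.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks run on every labeled 4-node graph plus 200 seeded
random graphs with N ≤ 30; generator recovery uses 20 seeds each of
preferential attachment (n = 600, m = 2), Erdős–Rényi (n = 1000, p = 0.01)
and the 125-node hierarchical construction; surrogate networks use the
published 156/260 skeleton. These sizes were chosen so the whole suite is a
desk-scale run while keeping every statistical assertion comfortably
powered.

## Known limitations

- The curated edge list itself is not distributed with the study, so
  edge-identity results (which specific receptors are relative-connectivity
  hubs, the exact module membership) cannot be recomputed, only the
  procedures validated.
- Least-squares fitting of raw P(k) on log–log axes is statistically biased
  for power-law tails; it is retained by design (see above).
- The classifier's three thresholds are heuristics; networks near the
  decision margin (e.g. configuration-model graphs with a short heavy
  tail) can legitimately fall on either side.
- MCODE results depend on documented tie-breaks; other implementations may
  order equal-score clusters differently.
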