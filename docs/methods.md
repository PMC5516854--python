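# Methods

## Problem and model

A signaling pathway is modeled as the set of routes by which a signal can
travel from any of a pathway's receptors (set *S*) to any of its
transcriptional regulators (set *T*) through a background interactome
*G* = (*V*, *E*). Each directed edge carries a weight *w*<sub>e</sub> ∈
(0, 1] interpreted as the probability that the interaction is real and
relevant; a path's score is the product of its edge weights, i.e. the joint
probability of the path under edge independence. The reconstruction is the
ordered union of the *k* highest-scoring loopless *S* → *T* paths, with each
node and edge ranked by the index of the first path containing it. Ranked
output is the point: cutting the list at any depth gives a subnetwork in
which every interaction provably lies on a receptor-to-TR route, and deeper
cuts only ever add interactions (the first-*k* edge sets are nested).

Assumptions worth stating: edge weights are treated as independent
probabilities (products are meaningful); weight 1 means a certain edge
(cost 0); signal direction matters, so the graph is directed and physically
undirected interactions must be expanded to both directions at ingest;
receptors and TRs may appear in the *interior* of a path — only endpoints
are constrained.

## Algorithm

Maximising a product of weights equals minimising the sum of per-edge costs
*c*<sub>uv</sub> = −log *w*<sub>uv</sub>. The natural log is used: any base
preserves the ordering, and *e* keeps `score = exp(-cost)` an identity. An
artificial source *s* gains a zero-cost edge to each receptor and each TR
gains a zero-cost edge to an artificial sink *t*, reducing the multi-source
multi-target problem to single-pair.

The *k* least-cost loopless *s* ⇝ *t* paths are computed with Yen's
algorithm. For each prefix (root) of the last emitted path, the next-edges
of every previously emitted path sharing that root are banned along with
the root's interior nodes, and a shortest deviation is computed from the
spur node; candidates live in a min-heap and are de-duplicated by full node
sequence. Spur searches are A\* searches guided by *h*(*v*) = the exact
least cost from *v* to *t*, precomputed once by Dijkstra on the reversed
graph. Because bans only remove edges and nodes, true remaining costs can
only grow, so *h* stays admissible (and consistent) in every spur search;
nodes with *h* = ∞ are never enqueued and each search stops the moment *t*
is popped. The heuristic is therefore a pure acceleration — measured at
roughly 1.5× on 30-node benchmarks here, and growing with graph size —
and result-identity with the unguided search is asserted, not assumed.

Degenerate *s* → *x* → *t* paths (a protein that is both receptor and TR)
contain no real interaction and are filtered; remaining paths are
re-indexed consecutively.

### Determinism and numerics

All cost ties are broken by the lexicographic order of the node sequence.
The search carries the partial sequence in its heap key — along a path both
the f-value (with a consistent heuristic) and the sequence are monotone
under extension, so the first pop of the target is the global minimum of
the product order (cost, sequence), for the guided and unguided variants
alike. Candidate path costs are recomputed as a single left-to-right sum so
a path's cost does not depend on how Yen's assembled it from root and spur.

One float caveat is documented rather than hidden: two genuinely tied paths
(e.g. both costing 5·ln 2) can differ in the last ulp because their sums
associate differently, in which case their relative order is float noise.
Tests therefore compare path *sets* within cost-tied clusters and enforce
exact order everywhere else; monotonicity assertions carry a 1e-12 slack.
With continuous random weights exact ties have probability zero and the
emitted order is fully determined.

Edge weights outside (0, 1] are rejected at ingest by default; an optional
`clamp_epsilon` (suggested 1e-10) replaces non-positive weights so −log
stays finite. Duplicate parallel edges collapse to the maximum weight;
self-loops are dropped (they can never lie on a loopless path).

## Baselines

**Shortest paths** — the union of one least-cost path per (receptor, TR)
pair under the same tie rule; a single subnetwork, no ranking.

**Random walk with restarts (RWR)** — a walk that restarts uniformly on the
receptor set with probability *q* (teleport, default 0.5) and otherwise
moves along out-edges with probability proportional to edge weight; dangling
nodes restart. The stationary distribution *p* is found by power iteration
to an L1 residual below 1e-10 (cap 10,000 iterations; non-convergence is an
error, not a silent result). Edges are ranked by stationary flux
*f*(*u*, *v*) = *p*(*u*) · *w*(*u*, *v*) / Σ<sub>x</sub> *w*(*u*, *x*),
descending, ties lexicographic. The defaults are explicit configuration:
the literature contains several RWR variants and this one is the package's
documented choice. Tests check the power iteration against a dense solve of
(I − (1 − q)·Mᵀ)·p = q·r, which is the independent oracle, never the
implementation.

## Evaluation protocol

Positives are the curated pathway's interactions restricted to the
interactome; negatives are a seeded uniform subsample of the remaining
interactions, `neg_ratio` (default 50) per positive, sampled from the
sorted candidate pool so the draw depends only on (seed, universe,
positives). Precision-recall is computed at each distinct rank threshold
with ties entering as blocks. Options mirror the standard protocol
variants:

* **Pathway-adjacent negative exclusion** — a negative touching at least
  one pathway protein is removed before subsampling. Since only potential
  false positives leave the denominator, precision at any fixed rank can
  only rise; the adjacency test uses the undirected skeleton because
  "adjacent" is about participation of pathway proteins, not signal
  direction.
* **Distance from pathway** — 0 for a true positive, 1 for an adjacent
  negative, otherwise 1 + the smaller endpoint's undirected hop distance to
  the nearest pathway protein (∞ if unreachable).
* **Recovery ranks** — for each receptor/TR, the first index of any ranked
  edge incident to it.
* **Role perturbation** — seeded removal or addition of a fraction
  (protocol value 0.3) of each role set, independently for *S* and *T*.
* **Protein-level evaluation** — node positives are the pathway proteins;
  node negatives are the endpoints of sampled negative edges that are not
  pathway proteins.
* **Aggregation** — micro-aggregation: (item, index) pairs from all
  pathways are pooled (items tagged per pathway, so one interaction in two
  pathways is two items) into a single curve.

## Synthetic fixtures

The generator emulates the *shape* of the real inputs: a directed G(n, p)
background with i.i.d. uniform weights, disjoint receptor and TR sets, and
a planted pathway of simple receptor-to-TR paths whose weights are drawn
well above background. Defaults — 200 nodes, edge probability 0.01 (mean
degree ≈ 2, sparse like real interactomes), 4 receptors, 4 TRs, 4 planted
paths of 2–3 edges, background weights U(0.05, 0.4), planted U(0.7, 0.95)
— make the planted routes the unambiguous top paths: the costliest planted
edge (−log 0.7 ≈ 0.36) is far cheaper than the cheapest background edge
(−log 0.4 ≈ 0.92).

Planted paths use disjoint interior nodes by default. This is deliberate:
if planted paths may share interior nodes, prefixes and suffixes of
different planted paths recombine into hybrid paths made entirely of
planted edges, and "the first |planted| paths recover exactly the planted
edges" stops being a well-defined ground truth. `shared_interiors=True`
restores sharing for convergence-style fixtures. Everything is a pure
function of the `FixtureSpec` (numpy PCG64; the generator name is recorded
in the fixture's JSON sidecar) — the same spec yields byte-identical files.

What the fixtures do **not** emulate: scale-free degree distributions, edge
weight correlations from shared evidence sources, pathway cross-talk, or
curation noise in the role sets. Passing the recovery tests shows the
engine ranks high-confidence routes correctly and the evaluation arithmetic
behaves as specified; it does not certify precision-recall levels on real
curated pathways.

## Problem sizes and defaults

`k` defaults to 20,000, reflecting heavy edge reuse among short paths in
real interactomes; tests and the acceptance script use 25–100 on synthetic
instances, which saturates them. The oracle sweep uses 500 random graphs of
4–10 real nodes (exhaustively enumerable), A\* neutrality 100 graphs of 30
nodes, recovery and protocol trends 20 fixture seeds each, and the RWR
oracle 50-node graphs; the full suite runs in seconds on one core.

## Known limitations

* Yen's with per-spur A\* is O(k·n·(m + n log n)) worst case; pure-Python
  sequence-carrying heaps trade constant-factor speed for determinism, so
  very large (k, interactome) combinations are slow compared to compiled
  implementations.
* The RWR dense transition matrix is O(n²) memory; adequate for the
  baseline's role here, not for genome-scale propagation.
* Edge weights are taken as given; estimating them from evidence sources is
  out of scope, as is any identifier mapping between naming systems.
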