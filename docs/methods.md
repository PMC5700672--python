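# Methods

## The model

`diffcentral` prioritizes candidate cancer genes by asking how much a gene's
*topological role* in the interactome changes between a patient's normal and
tumor tissue. Let `H` be the master undirected protein–protein interaction
network. For each patient instance `i` we induce two subgraphs of `H`:

* the **normal graph** `N_i`, on the genes called expressed in the normal
  sample (RPKM ≥ threshold, default 1, boundary inclusive), and
* the **tumor graph** `T_i`, on the genes called expressed in the matched
  tumor sample *minus* the genes with a non-silent somatic mutation in that
  sample.

All measures are functions over the node universe `V` — the union of the node
sets of every `N_i` and `T_i`. A gene absent from a graph scores 0 there.

### Unlabeled measures (rank descending: big change = interesting)

Each sums a per-graph centrality difference over all pairs:

    W_x(v) = Σ_i | x_{N_i}(v) − x_{T_i}(v) |

with `x` one of: normalized betweenness (`m_bw`, scaled by
`2/((|V|−1)(|V|−2))` so values lie in [0,1]; disconnected source/target pairs
contribute nothing; graphs with |V| < 3 score 0), clustering coefficient
(`m_cc`), degree (`m_deg1`), or the second-order neighborhood size (`m_deg2`,
where Ne²(v) = v's neighbors plus all of their neighbors — which includes v
itself whenever deg(v) ≥ 1; an `include_self=False` switch exists).

### Labeled measures (rank ascending: low similarity = interesting)

* `m_rw` / `m_gt`: for each pair, build a proximity matrix per graph — the
  ε-biased lazy random walk (`m_rw`) or the unweighted shortest-path distance
  matrix (`m_gt`) — and sum the Pearson correlation of the gene's column
  across the pair. Columns are re-indexed over a common node vector (default:
  the union of the pair's node sets; global-universe and shared-nodes modes
  are available) with zeros for absent entries. A constant (zero-variance)
  column yields correlation 0 — degenerate columns are treated as
  uninformative, not as changed.
* `m_j1` / `m_j2`: sum over pairs of the Jaccard index between the gene's
  order-1 (or order-2) neighborhoods in `N_i` and `T_i`; two empty
  neighborhoods count as identical (index 1).

The random walk iterates, from the origin's indicator vector,

    new(v) = Σ_{s ∈ Ne⁺(v)} max(0, old(s)/(deg(s)+1) − ε),

then renormalizes to a probability vector, stopping when the L1 change drops
below a threshold. The ε subtraction biases mass toward the origin; the
clamp at 0 is needed because a literal subtraction drives far-node
contributions negative. Defaults: ε = 1e-4, convergence threshold 1e-6,
max 1000 iterations (all CLI-exposed; the source procedure fixes none of
them). With ε = 0 the walk is the lazy random walk and converges to
π(v) ∝ deg(v)+1 on each connected component — the closed form the tests check
to 1e-6.

### Controls

`ed` (expression difference): |#normal samples expressing v − #tumor samples
expressing v|, counting expression calls only (a mutated-but-expressed tumor
gene still counts as expressed). `mf` (mutation frequency): the number of
tumor samples in which v is non-silently mutated (instances, not records).

### MWIS filtration

Influence-based measures suffer guilt by association: a gene can score high
because its neighbors do. To compress a ranking into genes that do not
explain each other, the interactome over `V`, node-weighted by the measure,
is filtered with the GWMIN2 greedy heuristic for the NP-complete maximum
weight independent set problem: repeatedly select the node `u` maximizing
`W(u) / Σ_{v ∈ N⁺(u)} W(v)` (closed neighborhood, recomputed on the residual
graph each round — greedy with deletion, matching the heuristic literature),
then delete `N⁺(u)`. Ties break by larger weight, then lexicographic id.
The output weight provably reaches at least `Σ_u W(u)²/Σ_{v∈N⁺(u)} W(v)`,
which `gwmin2_bound` computes and the tests assert. Ascending-direction
measures are flipped to non-negative importances (`w' = max − w`) before
filtering. Nodes whose closed-neighborhood weight sum is 0 carry no evidence:
they are excluded from the argmax and appended only if isolated after the
main loop, so they never block weighted neighbors.

## Evaluation harness

**Top-k% ROC/PR.** A ranking is thresholded at every integer percentile
k = 1..100 (prefix size `ceil(k·n/100)` — ceil keeps k = 1% non-empty on
short lists); each prefix is a classifier over the universe, and AUROC/AUPR
come from trapezoidal integration over the sweep points (ROC anchored at
(0,0) and (1,1); PR recall-anchored at 0 with the first precision). A
`full_resolution` mode thresholds at every rank instead. Gold standards are
intersected with the universe first, the standard convention in
prioritization evaluation.

**GO consistency.** Annotations are standardized to one DAG level (default
5, where a term's level is the shortest directed path, in edges, to the
ontology root over `is_a` + `part_of` edges — configurable, since "level" has
no universal definition): shallower annotations are dropped as too generic,
deeper ones are replaced by *all* of their ancestors exactly at the level.
Then

    GOC(T, R) = [ Σ_{t∈T} Σ_{r∈R} |GO(t)∩GO(r)| / |GO(t)∪GO(r)| ] / |R|.

GOC is linear in the test list, which the tests exploit as an invariant.

**Rewiring robustness.** `rewire` removes `round(r% · |E|)` edges uniformly
and inserts the same number between uniformly sampled pairs that are
non-adjacent in the *original* network (so removed edges are never
reinserted), rejecting self-loops, duplicates and pairs adjacent in the
evolving result; node set and edge count are preserved and the operation is
seed-reproducible. The experiment driver rebuilds every pair on each rewired
network, recomputes the measures, and averages AUROC/AUPR per ratio over
replicates (default ratios 5/10/15/20%, 4 replicates). With 99 instances,
4 ratios and 4 replicates the driver constructs exactly
2·99·4·4 = 3168 induced graphs, which it reports.

## Synthetic cohorts

The generator emulates the *shape* of the study inputs, not their values:

* **Interactome**: preferential attachment (Barabási–Albert, default 500
  genes, attachment degree 2) — connected, heavy-tailed like real PPI
  networks. Gene ids are assigned by a seeded permutation so identifier
  order carries no degree information (preferential attachment otherwise
  grows hubs at the earliest indices, and the deterministic lexicographic
  tie-break would leak rank signal into tie-heavy measures).
* **Drivers**: the `n_drivers` = 15 highest-degree hubs. In each tumor
  sample, with probability `driver_dropout` = 0.6 per driver, a random half
  of the driver's partners (default mode `"neighbors"`) is removed from the
  tumor-expressed set. This perturbs the driver's induced-subgraph
  neighborhood — the signal differential centrality responds to — while
  leaving the driver's own expression intact, so the expression-difference
  control cannot see the planted signal trivially. Modes `"driver"`
  (remove the driver itself) and `"mixed"` exist.
* **Noise**: independent 2% expression flips per gene per sample (tumor
  flips applied on top of the normal set) and 1% per-gene non-silent
  mutation calls per tumor sample; mutated genes leave the tumor graph, as
  in the real pipeline.
* **Toy GO**: a depth-8 DAG whose levels are exact by construction; gold
  genes draw from a dedicated block of level-5 terms (sometimes via a
  level-7 descendant, which level restriction must resolve back up),
  background genes from a disjoint pool with a 5% cross-annotation chance.
* 40 instances by default; the defaults are what the acceptance checks run.

What passing on this cohort does **not** show: recovery of real BRCA genes.
Real expression is not binary-with-uniform-flips, real mutation rates are
gene- and length-dependent, real interactomes have study bias and false
edges beyond uniform rewiring, and real drivers are not simply hubs. The
synthetic results demonstrate the machinery's correctness and the measures'
qualitative ordering (differential centrality ≫ expression/mutation-count
controls under topological perturbation), not clinical performance.

## Numerical choices and degenerate inputs

* Betweenness on graphs with |V| < 3 is defined as 0 (normalization
  undefined); σ_st = 0 pairs (disconnected) contribute 0.
* Distance-matrix sentinel for unreachable pairs is 0, mirroring the
  absent-node convention; a `|V|` sentinel mode avoids conflating "self"
  with "unreachable".
* Pearson correlation of a constant vector is defined as 0.
* Rankings sort by weight with a lexicographic gene-id tie-break, so every
  output is byte-reproducible.
* Walk iteration raises (naming ε) if clamping zeroes an entire vector.
* All generators/rewiring accept integer seeds; equal seed ⇒ identical
  output, which the CLI records in a per-run `manifest.json` together with
  input SHA-256 digests.

## Problem sizes

The bundled checks run at desk scale by choice: driver recovery on the
default 500-gene / 40-instance cohort; the rewiring trend on a 150-gene /
12-instance cohort (4 replicates × 5 ratios); the 3168-graph bookkeeping on
a 40-gene / 99-instance cohort with the degree measure. The exhaustive MWIS
oracle in the tests covers graphs up to 15 nodes; brute-force betweenness
up to 8.

## Known limitations

* The ε-decrement walk is implemented as specified, not replaced by the
  standard restart-probability formulation; the two are related but not
  equivalent.
* No edge- or node-weighted centrality generalizations; no identifier
  mapping between id spaces (inputs must share one id column).
* `m_rw` over large cohorts is the slowest measure (dense per-graph matrix
  iteration); use `m_gt` for a cheaper labeled proxy.
* Whether the original study's Pearson vectors spanned the pair union, the
  global universe, or only shared nodes is not stated; all three are
  implemented, default pair union.
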