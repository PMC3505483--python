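# Methods

## Data model

A heterogeneous biological graph is effectively undirected but carries
directed edge-type labels: every edge type has an inverse (`codes_for` /
`coded_by`; a symmetric type like `interacts_with` is its own inverse).
Each relation is stored once, in a canonical direction — the orientation
with the lexicographically smaller `(source_type, edge_type, source_id)`
tuple — and queried from either endpoint, the reverse query reporting the
inverse type.  Parallel edges between the same node pair are collapsed to
one edge keeping the **maximum** reliability (the strongest evidence);
self-loops are rejected at load time since no modeled relation is
reflexive.  The degree of a node counts each undirected relation once, not
once per direction; the linktype-specific degree counts only incident edges
whose type *as seen from that node* matches, so both endpoints of a
directed type are treated symmetrically.

The on-disk format is a TSV edge list
(`source_id  source_type  edge_type  target_id  target_type  reliability`)
with `#` comments and an optional header; it round-trips exactly.

## Edge weighting

Weights combine relevance, informativeness and reliability by product,
`p(e) = q(e)·i(e)·r(e)`, capped at 1 for the probabilistic measures and
uncapped for the random walk.  Defaults: α = 0.25 for the degree penalty
(steeper penalties flatten hub influence too aggressively; α = 0 disables
the penalty entirely), linktype-independent degrees, default relevance 1.
Informativeness is computed on the unweighted topology — degrees, not
weighted degrees — and on the *full* graph before any neighborhood
bounding, so bounding never changes weights.

## Proximity measures

**Best path** is exact: a Dijkstra shortest path under −log weights;
zero-weight edges are treated as absent everywhere.

**Network reliability** and **expected reliable distance (ERD)** are
#P-hard exactly, so they are estimated by Monte Carlo over independent
edge realizations (default 10,000 samples), optionally on a bounded
neighborhood subgraph (nodes within a hop limit of the terminals, truncated
to the highest best-path-probability nodes; default bound when enabled:
1,000 nodes, depth 4).  Samples are grouped by realized edge mask, so on
small subgraphs connectivity is evaluated once per distinct realization.
The standard error reported for reliability is the binomial
`sqrt(v(1−v)/n)`.  ERD is the hop-count shortest-path distance conditioned
on connection; if no sampled realization connects the pair it is flagged
undefined rather than given a value.  An exhaustive 2^|E| oracle (≤ 20
edges) provides exact values for testing; it is the independent check, not
the production path.

**Random walk with restart** uses restart probability β = 0.2 (roughly
matching the q = 0.8 uniform-relevance baseline of the probabilistic
measures).  The exact method solves the stationary system
`(I − (1−β)Pᵀ)π = β·e_s` with a sparse LU factorization cached per weighted
graph, so scoring many roots on one graph costs one factorization plus one
back-substitution per root.  Dangling nodes (no positive-weight incident
edge) force a restart; in an undirected graph they are unreachable from any
other root, so this is implemented in closed form: their stationary mass is
zero, and a dangling root yields the point mass π = e_s.  The reported
score is the symmetric average (π_s(t) + π_t(s))/2.  The simulation method
runs an explicit walk (default 10⁶ steps) counting every step as a visit,
restart steps included — the convention matters only in the third decimal
but is fixed for reproducibility.

All stochastic operations take an explicit seed and are bit-for-bit
reproducible given it.

## Link prediction and evaluation

Pairs are ranked by proximity; ERD, being a distance, is ranked by its
negative with undefined values ranked last.  Pairs naming nodes absent from
the graph score 0 with a warning instead of erroring — real candidate lists
contain unindexed entities, and dropping them silently would bias the AUC.

ROC curves process tied scores as one group (a diagonal segment), so the
trapezoidal AUC equals the Mann–Whitney statistic with half-credit for
ties — the convention consistent with AUC's probabilistic interpretation.
Two score vectors over the same pairs are compared with the DeLong paired
test on placement values; the tests validate its p-values against a
10,000-draw paired sign-flip permutation oracle.

Negative pairs are sampled uniformly from pairings of nodes that appear
among the positives (keeping negatives as well-studied as positives),
excluding the positives themselves and anything matching a caller-supplied
exclusion predicate — the predicate is injectable because which linked
pairs must be excluded is application-specific.

Relevance tuning varies one edge type at a time over a grid with all others
at default (after applying any pinned coefficients, e.g. `codes_for` = 10),
assigning each type its AUC-maximizing value unless the improvement is
below 0.002 AUC — the operationalization of "no noticeable effect".  The
heuristic deliberately ignores interactions between types; as a guard the
combined map is evaluated once on the training pairs and the baseline map
is kept if the combination underperforms, so tuning can never return a map
worse than its starting point on the training data.

## Prioritization

The proximity backend for prioritization defaults to the random walk
(β = 0.2, uncapped weights), which performs best among the four measures on
the planted-structure benchmarks here.  The classifier scores never read
the proximity-matrix diagonal (all sums are over s ≠ t).

The leave-one-out supervised protocol scores each positive against the
other positives and each negative as the *exact* average over all
size-(|S_P|−1) subsets of S_P — the strictest reading of using every subset
equally often — so every candidate sees the same reference-set size.  It is
an evaluation protocol (it needs truth labels), not a field method; with an
external reference set the plain supervised score applies.

The cluster score sums (p(s,t) − q) over **ordered** pairs, i.e. twice the
unordered sum under symmetry; the factor only rescales q and does not
change which subsets win at a fixed q.  The greedy search initializes each
candidate into the cluster with probability ½, applies the single-element
move with the largest score improvement (ties broken toward the smallest
node id) until no move improves, and keeps the best terminal state over 100
restarts; each applied move strictly increases the score, so termination is
guaranteed.  The incremental attachment-sum update makes a restart
O(moves × |S|).  On random 12-candidate instances the search matches
exhaustive 2¹² enumeration ≥ 95% of the time and never exceeds it.

The cluster classifier yields one (FPR, TPR) point per sensitivity q; the
pseudo-ROC averages per-case rates over many cases at each q on a grid.
Unlike a ranking ROC it need not be monotone and is returned as-is, without
an AUC.

## Synthetic data

The generator emulates an integrated-database graph at desk scale.  The
default configuration — fixed once and used by the tests and the acceptance
script — has 1,800 nodes (700 genes, 600 proteins, 150 pathways, 350
articles) and six edge types.  Background edges attach endpoints with
probability ∝ (degree + 1)^skew, giving heavy-tailed degrees with article
and pathway hubs.  Curated types (`codes_for`, `interacts_with`,
`participates_in`, `refers_to`) carry reliability 1.0; predicted
associations (`associated_with`) draw reliabilities from Beta(4, 2)
(mean 2/3), echoing that only predicted edges carry sub-unit confidences.

Twenty families of eight genes each are planted by wiring members to two
dedicated pathway nodes (each membership edge present with probability
0.9), with 3% cross-family membership noise; members are thus mutually
proximal through *shared annotations*, not necessarily direct edges, which
is what makes multi-hop proximity necessary.  Direct within-family
`related_to` edges are created with probability 0.6, and half of them are
removed into a hidden truth as "future links" — the positives for link
prediction.  Negatives are sampled among positive-set nodes excluding
anything linked in either the visible or hidden graph.  Prioritization
cases draw S_P from one family and S_N from the union of the other
families, mirroring the control choice that avoids degree bias; the
baseline setting is |S_P| = 5, |S_N| = 15, with |S_N| varied over
{5, 15, 25, 35, 45}.

What the generator does *not* emulate: the real databases' absolute scale
(10⁶ nodes), their full type vocabulary, text-derived edges, and their
empirical degree mixtures.  Passing the planted-structure tests therefore
demonstrates that the measures and classifiers recover the kind of signal
the model assumes (relatedness expressed as multi-hop graph proximity), not
that they achieve any particular accuracy on real data.

## Problem sizes in the tests and acceptance script

Oracle comparisons use 50–100 random graphs with ≤ 10 edges and 20,000
Monte-Carlo samples; cluster optimality uses 100 random 12-candidate
instances against exhaustive enumeration; planted link prediction averages
50+50 labeled pairs over 10 generator seeds; prioritization uses 15 cases
per negative-set size.  These sizes give stable statistics (binomial SE on
an AUC from 10×100 pairs is well under 0.02) while keeping the whole suite
in the tens of seconds on one CPU.

## Known limitations

* Exact network reliability is only available up to 20 edges; large-graph
  estimates depend on the neighborhood bound, which truncates by best-path
  probability and can in principle exclude high-reliability multi-path mass.
* The DeLong test's normal approximation is inaccurate for very small pair
  sets (tens of pairs) or AUCs at the boundary.
* The one-at-a-time tuning heuristic cannot express interactions between
  edge-type relevances.
* The greedy cluster search is a local method; its ≥ 95% exhaustive-match
  rate is measured on uniform random proximity matrices and may be lower on
  adversarial inputs.
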