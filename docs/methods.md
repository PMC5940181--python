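# Methods

## Problem setting

A drug–drug interaction (DDI) network is an undirected simple graph
G(V, E): nodes are drug identifiers (opaque, case-sensitive strings),
edges are known interactions with direction ignored.  The universal pair
space U holds |V|(|V|−1)/2 unordered pairs; candidate interactions live in
U − E.  Link prediction scores each candidate pair and is evaluated here
as balanced binary classification: positives are observed edges, negatives
are pairs sampled uniformly from U − E (1:1 by default), and examples are
split 66/33 (stratified) into train and test.

## Pair similarity features

Twelve features per pair, in fixed column order
`cn, jc, aai, pa, rai, ccn, cra, wic, atc, chem, mesh, ade`.

**Topological.**  With Γ(x) the neighbor set, d(z) = |Γ(z)| and
Λ = Γ(x) ∩ Γ(y): common neighbors |Λ|; Jaccard |Λ|/|Γ(x) ∪ Γ(y)| (0 for
an empty union); Adamic/Adar Σ 1/ln d(z) (natural log — every common
neighbor of a simple-graph pair has degree ≥ 2, so the log never
vanishes); preferential attachment d(x)·d(y); resource allocation
Σ 1/d(z).  Empty-Λ sums are 0.

**Community-aware.**  `ccn` adds to |Λ| one point per community shared by
x, y and each common neighbor i, counted on the *overlapping* community
view C(·); `cra` scores each common neighbor (1 + |C(i) ∩ C(x) ∩ C(y)|)/d(i);
`wic` uses the *partition* view: common neighbors in the same partition
community as both endpoints count as within-cluster (Λ_W), the rest as
inter-cluster, and the score is |Λ_W|/(|Λ_IC| + δ).  δ defaults to 0.001
(configurable); it only bounds the score when no inter-cluster common
neighbor exists.  If x and y sit in different partition communities,
Λ_W = ∅ and the score is 0.

Community detection is greedy modularity maximization by default — a true
partition; the overlapping view then holds singleton sets, under which
`ccn` = 2·`cn` and `wic` = `cn`/δ when the whole graph is one community.
A k-clique percolation method (k = 3) supplies genuinely overlapping
memberships when wanted; nodes outside every clique community become
singletons, and its partition view takes each node's lowest community id.
Which detection algorithm "should" be used is under-determined in this
literature, so the assignment is an explicit, swappable input to the
featurizer and the method tag travels with the assignment.

**Semantic.**  Each of three code channels (therapeutic classification,
literature indexing terms, side effects) represents a drug as a binary
code vector weighted by IDF(t) = ln(|D|/n_t), where |D| is the number of
drugs *in that channel's catalog* (not the network's node count) and n_t
the number carrying code t; pair similarity is the cosine of the two
weighted vectors.  The log base is immaterial to the cosine; natural log
is fixed so stored weights are reproducible.  The chemical channel
compares fixed-length binary fingerprints (1024 bits by default) with the
Tanimoto coefficient c/(a + b − c), identical to Jaccard similarity on the
supported-bit sets.  A drug absent from a channel, or any zero-norm
vector, scores 0 with a missing flag; missingness is data, counted and
reported, never an error.  An optional adapter builds Morgan fingerprints
from SMILES when rdkit is present; the core pipeline consumes precomputed
bitstrings so no chemistry stack is needed.  Hierarchical therapeutic
codes can be truncated to their first level via a catalog-loading switch;
the default keeps full codes.

## Classifiers

**Combined score (unsupervised).**  Features are z-scored with means and
standard deviations learned from the reference rows (zero-spread features
contribute 0), averaged into one score per pair, and thresholded at the
90th percentile of the fitting scores — nearest-rank definition, strict
`>`, so a score exactly at the threshold is not a link.  The threshold is
frozen at fit time by default; a `refit_threshold` switch recomputes it on
each scored set, matching the workflow in which train and test sets are
thresholded independently.  Labels are never used in fitting; the
construction makes the score invariant under any affine rescaling of an
input feature.

**Supervised harness.**  Five families behind one estimator:
classification tree (depth grid 2–16/none), k-nearest neighbors
(Euclidean, k ∈ {1, 3, …, 25}, features standardized), linear-kernel SVM
(penalty C ∈ {0.01, 0.1, 1, 10}, standardized, Platt-style calibration for
[0, 1] scores), random forest (500 trees), gradient boosting (150 trees,
depth 3, learning rate 0.1 — shallow-and-many in the usual boosting
regime).  Hyperparameter grids are searched by stratified 5-fold
cross-validation maximizing accuracy; the tuned model refits on the full
training set.  For selection *across* families, a 10-fold CV accuracy of
the tuned configuration is available (`compute_selection_score=True`,
stored as `selection_score_`); it is off by default because single-family
runs do not need it.  All cross-validation folds and learners are seeded;
the same seed reproduces the same selected hyperparameters exactly.
Continuous scores are class-1 probabilities; hard labels use 0.5.
Impurity-decrease (Gini) importances from the tree ensembles are reported
absolutely and min-max normalized to 0–100 and 0–1.

## Featurization modes and leakage

Two modes, recorded in every table's provenance:

* **paper** — balanced pairs are built on the full network, topological
  features are computed on the full graph, and the 66/33 split stratifies
  labeled examples.  Positive test pairs' own edges are visible to the
  featurizer (e.g. `pa` counts the partner in the degree), which inflates
  test scores; this is the classical workflow and is kept for
  comparability.
* **leakage-safe** — edges are split 66/33 first, test edges are removed
  from the graph before featurization (communities are likewise detected
  on the training graph), and train/test positives are the train/test
  edges.  Negatives are sampled against the *full* edge set in both modes,
  so no sampled negative is ever a known interaction.

## Statistical comparison

Per network and classifier: precision, recall, F1, the four confusion
rates (TPR/FPR/TNR/FNR; zero-denominator ratios propagate as NaN, never
silent zeros), AUROC and AUPR by trapezoidal integration over distinct
score thresholds (AUPR integrates the precision–recall curve itself, not
average precision — one fixed convention, recorded here).

Across networks, classifiers are compared by within-network ranks (rank 1
= best, average ranks on ties) with the classic Friedman statistic
χ² = 12N/(k(k+1)) Σ_j (R̄_j − (k+1)/2)², df = k − 1, **without** a
tie-correction factor — the variant that exactly reproduces the published
benchmark values 18.4 and 17.72 from the printed AUPR matrices, including
the tied cell in the test matrix.  When the omnibus test rejects, the
Nemenyi post-hoc refers standardized mean-rank differences to the
studentized-range distribution (infinite df); the critical difference at
α = 0.05 is q_α √(k(k+1)/(6N)) with q_α the studentized-range quantile
divided by √2.  Pairwise p-values depend on the tie-handling and
quantile approximation of the implementation, so only the χ² statistics —
not individual post-hoc p-values — are treated as exactly reproducible.

Diagnostics: the Kruskal–Wallis rank-sum test contrasts the per-pair mean
of z-scaled features across positive-labeled, negative-labeled and freshly
sampled random pairs; feature columns are clustered with Ward linkage on
Euclidean distances after z-scaling (each feature a point, pairs the
coordinates; constant columns become zero vectors).

## Synthetic data generator

The generator emulates the regime of curated interaction networks — giant
component ≈ 1, high clustering, short paths, heavy-tailed degrees — with a
degree-corrected planted partition: n drugs (default 500) in equal-size
communities (default 5), edge probability p_in (0.3) within and p_out
(0.01) between communities, multiplied by per-node propensities drawn from
a unit-mean Pareto with tail exponent 2.5 (probabilities clipped at 1;
`degree_exponent=None` disables the correction for homogeneous graphs).
Defaults give |E| ≈ 5000–5500, clustering ≈ 0.39, mean path ≈ 2.3, giant
component 1.0 — and the full pipeline on one such dataset runs in well
under a minute on one CPU, which is why the default size was chosen.

Attribute channels couple to the communities through the signal knob
λ ∈ [0, 1]: every community owns a disjoint pool of codes inside a global
vocabulary (per-channel sizes 70/150/200, per-drug set sizes 4/8/10), and
each drawn code comes from the community pool with probability λ, else
from the global vocabulary.  Fingerprints blend a per-community prototype
bit pattern with global noise at the same rate (density 0.1).  At λ = 1
attribute similarity is maximally aligned with community (and hence link)
structure; at λ = 0 it is independent of the network by construction.
Per-channel missingness rates drop drugs from catalogs.  Generation is
fully deterministic given the config seed.

What the generator does **not** emulate: real chemistry (fingerprints are
abstract bit patterns, not molecular substructures), hierarchical code
vocabularies, inter-database identifier noise, or any specific database's
degree sequence.  Passing tests therefore demonstrate that the machinery
recovers planted structure of this kind, not that any particular accuracy
will be attained on real curated databases.

## Null condition

The no-signal check (λ = 0, p_in = p_out, degree correction off) is run in
**leakage-safe** mode.  In paper mode even a signal-free graph yields
above-chance test AUROC (≈ 0.58) because each positive pair's own edge
inflates its endpoints' degrees — a purely mechanical artifact, which the
leakage-safe mode exists to remove; with it removed, held-out AUROC sits
at chance (≈ 0.5) as the construction demands.  The full-signal check
stays in paper mode, matching the classical workflow it mirrors.

## Numerical and interface conventions

* Splits: training count = floor(fraction × n), remainder to test;
  stratified per-class counts likewise floor with ties toward training.
* Negative sampling: uniform without replacement via rejection sampling
  capped at 50× the requested count, then exact enumeration of U − E
  (exactness on small or dense graphs, speed on large sparse ones).
* Every operation draws randomness from a named per-stage seed derived
  from one root seed (CRC of "root:stage"), so adding a stage never
  perturbs earlier stages.
* Overlap proportion between edge sets = shared / min(|E_A|, |E_B|);
  undefined (NaN) when a member has no edges.  Mean degree = 2|E|/|V| on
  whatever edge set was loaded.
* Diameter and mean path length are hop counts on the giant component
  (BFS; averaged over connected ordered pairs); mean clustering counts
  degree < 2 nodes as 0; edgeless graphs report NaN path statistics.
* Edge-list files are two-column TSV, `#` comments allowed; the writer
  canonicalizes pairs lexicographically and sorts lines, so save/load
  round-trips are byte-stable.

## Known limitations

* Greedy modularity is deterministic but not optimal; community-dependent
  features (`ccn`, `cra`, `wic`) are only as reproducible as the
  assignment they are given.
* The combined score weights all twelve z-scored features equally; a
  channel that is pure noise on a given dataset dilutes it.
* Nemenyi p-values use the infinite-df studentized range without tie
  correction of the underlying ranks beyond averaging.
* The pipeline holds feature tables in memory; networks with ≳10⁵ edges
  produce pair tables that may warrant chunked featurization.
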