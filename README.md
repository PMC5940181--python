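# ddilink

Link prediction on drug–drug interaction (DDI) networks.

Co-administered drugs can alter each other's pharmacologic effect, and most
interaction databases are known to be incomplete.  `ddilink` treats the
discovery of unknown interactions as binary classification of drug *pairs*
on an undirected interaction network G(V, E): each candidate pair (x, y)
gets a 12-dimensional feature vector of pair similarities, and a classifier
scores how likely the pair is to interact.  It is written for computational
pharmacology / network-biology researchers who want a tested, reusable
version of this workflow that runs on plain TSV inputs.

## The method

**Topological features** (Γ(x) = neighbors of x, Λ = Γ(x) ∩ Γ(y),
d(z) = |Γ(z)|):

| feature | definition |
|---|---|
| `cn`  | common neighbors, \|Λ\| |
| `jc`  | Jaccard coefficient, \|Λ\| / \|Γ(x) ∪ Γ(y)\| |
| `aai` | Adamic/Adar, Σ_{z∈Λ} 1/ln d(z) |
| `pa`  | preferential attachment, d(x)·d(y) |
| `rai` | resource allocation, Σ_{z∈Λ} 1/d(z) |
| `ccn` | community common neighbors, \|Λ\| + Σ_{i∈Λ} \|C(i) ∩ C(x) ∩ C(y)\| |
| `cra` | community resource allocation, Σ_{i∈Λ} (1 + \|C(i) ∩ C(x) ∩ C(y)\|)/d(i) |
| `wic` | within/inter-cluster ratio, \|Λ_W\| / (\|Λ_IC\| + δ) |

C(n) is the set of communities node n belongs to (greedy modularity
partition by default, overlapping k-clique optional); Λ_W are common
neighbors sharing the pair's partition community, Λ_IC the rest, δ = 0.001.

**Semantic features**: IDF-weighted cosine similarity over three per-drug
code channels — therapeutic classification (`atc`), literature indexing
terms (`mesh`), side effects (`ade`) — with IDF(t) = ln(|D|/n_t), plus the
Tanimoto coefficient c/(a + b − c) over 1024-bit binary fingerprints
(`chem`).

**Classifiers**: an unsupervised *combined score* (mean of the z-scored
features, link predicted when the score exceeds the 90th nearest-rank
percentile) and five tuned supervised families — classification tree,
k-nearest neighbors, linear-kernel SVM, random forest, gradient boosting —
with cross-validated hyperparameter selection.  Training sets are balanced
by uniform negative sampling from the non-edge space U − E, then split
66/33 (stratified).

**Comparison framework**: precision/recall/F1/AUROC/AUPR per network and
classifier; the Friedman rank test
χ² = 12N/(k(k+1)) Σ_j (R̄_j − (k+1)/2)² across networks, followed by the
Nemenyi post-hoc with critical difference CD = q_α √(k(k+1)/(6N));
Kruskal–Wallis contrast of positive / negative / random pair similarity;
Ward/Euclidean feature dendrograms.  Gini-impurity feature importances are
reported for the tree ensembles.

A synthetic-data module generates DDI-like datasets (degree-corrected
planted-partition networks plus attribute channels coupled to the
community structure by a signal knob λ), so the whole pipeline is testable
without access to any licensed database.

## Worked example

```python
import ddilink as dl

# a synthetic dataset: 500 drugs, 5 communities, full attribute signal
ds = dl.generate(dl.SynthConfig(seed=1))
stats, _ = dl.summarize(ds)
print(stats.to_row())
# {'network': 'synth-seed1', 'n_nodes': 500, 'n_edges': 5140,
#  'avg_degree': 20.56, 'diameter': 4.0, 'avg_path_length': 2.2716...,
#  'clustering': 0.3854..., 'giant_component': 1.0}

report = dl.run(dl.RunConfig(mode="paper", seed=1,
                             classifiers=("random_forest",),
                             synth=[{"seed": 1}]))
print(report.metrics[report.metrics.subset == "test"]
      [["classifier", "precision", "recall", "f1", "auroc", "aupr"]]
      .round(2).to_string(index=False))
#    classifier  precision  recall   f1  auroc  aupr
#  unsupervised       0.98    0.22 0.36   0.91  0.90
# random_forest       0.83    0.86 0.85   0.92  0.93
```

The unsupervised combined score is precise but recalls only the top decile
of pairs by construction; the tuned random forest recovers the planted
interaction structure far more completely (F1 0.85 vs 0.36) and edges it
on area under the precision–recall curve.

The same run from a shell:

```bash
ddilink synth --n-drugs 500 --seed 1 --outdir data/
ddilink stats data/edges.tsv
ddilink compare aupr_matrix.csv   # Friedman + Nemenyi on a CSV matrix
ddilink run --config run.yaml --outdir results/
```

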