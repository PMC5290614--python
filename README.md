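# treelandscape

Visualize and compare **landscapes of phylogenetic trees**: large collections
of trees (typically bootstrap replicates from many gene partitions of one
alignment) mapped into 2D or 3D so that the distance between plotted points
reflects the topological distance between trees. Well-separated clusters in
such a landscape reveal gene partitions whose bootstrap trees disagree —
a diagnostic for substitution-model misfit or failed tree searches — while a
single diffuse cloud is what perfect models of a shared history would produce.

The package is aimed at molecular phylogeneticists who have sets of Newick
trees and want to (1) build tree-to-tree distance matrices, (2) embed them
with nonlinear dimensionality reduction (NLDR), (3) check whether 2 or 3
dimensions can represent the distances at all, (4) quantify how faithful an
embedding is, and (5) summarize and compare clusters across landscapes.

## What it computes

**Robinson–Foulds distances.** For unrooted trees T₁, T₂ on the same leaves,
δ(T₁,T₂) = |B(T₁) Δ B(T₂)|, the number of non-trivial bipartitions (splits)
present in one tree but not the other. Splits are bitmask-encoded over a
fixed leaf ordering, so the all-pairs matrix over thousands of trees is fast
and exact. Externally computed matrices (square CSV or PHYLIP
lower-triangular) are accepted everywhere a matrix is needed.

**Four stress functions** measuring the discrepancy between input distances
δᵢⱼ and embedded Euclidean distances dᵢⱼ (sums over pairs i &lt; j):

| stress | definition |
|---|---|
| normalized | Σ(δ−d)² / Σδ² |
| Kruskal-1 | √( Σ(δ−d)² / Σd² ) |
| Sammon / NLM | (1/Σ′δ) Σ′ (δ−d)²/δ  (δ=0 pairs excluded) |
| CCA | Σ(δ−d)² F(d,λ),  F(d,λ)=1 if d ≤ λ else 0 |

The CCA weight depends on the *output* distance, which lets the embedding
"tear" the distance manifold: pairs pushed beyond the shrinking neighborhood
radius λ stop contributing, so local structure is preserved without dragging
distant clusters together.

**Five optimizers** — majorization (SMACOF), Gauss–Seidel–Newton, stochastic
gradient descent, MCMC simulated annealing, and Linear Iteration (fixed-step
steepest descent on Kruskal-1) — in exactly **14 admissible stress×optimizer
pairings** (CCA is paired only with SGD and MCMC; Kruskal-1+SGD is replaced
by Linear Iteration), each run from multiple random starts.

**Intrinsic dimensionality** of a distance matrix by four routes: correlation
dimension (log–log slope of the pair-count curve C(r)), the Levina–Bickel
maximum-likelihood estimator, the Pettis nearest-neighbor estimator with its
Gamma-function bias correction, and the stress-vs-dimension curve.

**Embedding diagnostics**: trustworthiness and continuity (rank-based
penalties for spurious and lost neighbors), nearest-neighbor label agreement
(1NN), and ordinary Procrustes comparison of replicate runs with automatic
flagging of non-equivalent projections.

**Convex-hull summaries**: per-partition hulls after variance-threshold
outlier pruning (a point is dropped when excluding it lowers the variance of
within-group pairwise distances by more than a fraction τ, default 0.01),
with rigid hull translation away from the origin to reveal interior clusters.

## Worked example

Simulate a clustered landscape (5 partitions × 40 trees on 20 taxa, shorter
partitions more scattered), build the RF matrix, embed with CCA+SGD in 3D
from 10 random starts, and score the result:

```
$ treelandscape simulate --taxa 20 --partitions 5 --trees-per 40 --seed 1 --out trees/
$ treelandscape rfdist trees/ --out rf.csv --labels-out labels.tsv
$ treelandscape nldr --distances rf.csv --labels labels.tsv \
      --stress cca --optimizer sgd --dim 3 --restarts 10 --seed 42 \
      --out landscape.csv --run-log runs.csv
INFO cca+sgd p=3: best stress 9.42201e-25 (mean 10.0097, se 5.2 over 10 restarts)
$ treelandscape evaluate --distances rf.csv --embedding landscape.csv --labels labels.tsv
{
  "one_nn": 0.99,
  "one_nn_ceiling": 1.0,
  ...
  "trustworthiness_k": { "1": 0.9825, "5": 0.963234375, ... }
}
```

`one_nn = 0.99` means 99% of trees have a nearest neighbor *in the 3D
landscape* from their own partition (the same statistic computed on the raw
RF matrix — the attainable ceiling — is 1.0), and trustworthiness ≈ 0.96 at
k = 5 means the embedding invents almost no spurious neighborhoods: the
five gene-tree clusters survive the projection. Continuity is lower
(≈ 0.72 at k = 5) because CCA deliberately tears long-range structure while
protecting local neighborhoods.

Intrinsic dimensionality of a known 3D point cloud, for calibration:

```
$ treelandscape simulate-manifold --kind cube --n 1000 --seed 1 --out cube.csv
$ treelandscape dim --distances cube.csv --methods nn,cor,ml
{
  "ml_estimate": 3.313904636273538,
  "nn_estimate": 2.8719468553230185,
  "cor_estimate": 2.6605152920709862
}
```

All three estimators land near the true dimension 3. The same command on an
RF matrix reports how many dimensions the tree distances intrinsically need.

The whole chain (`rfdist → nldr → evaluate → hulls`) also runs as one
command: `treelandscape pipeline --trees trees/ --stress cca --optimizer sgd
--dim 3 --outdir out/`.

As a library, the embedder is a scikit-learn-style estimator:

```python
from treelandscape import NLDREmbedding, rf_matrix, read_treeset

ts = read_treeset(["gene1.nwk", "gene2.nwk"])
dm = rf_matrix(ts)
X = NLDREmbedding(n_components=3, stress="cca", optimizer="sgd",
                  random_state=0).fit_transform(dm.delta)
```

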