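# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `treelandscape`, in the order the pipeline runs them.

## Tree representation and RF distances

Trees are parsed with dendropy and treated as unrooted topologies
throughout; rooted Newick input is accepted and a degree-2 root is
ignored by construction. Each tree is canonicalized to its set of
non-trivial bipartitions, encoded as integer bitmasks over the
lexicographically sorted leaf labels and complement-normalized so the bit
of the first leaf is always 0. Set operations on splits are then exact
integer comparisons, and the Robinson–Foulds distance is the size of the
symmetric difference of two split sets, computed as
|A| + |B| − 2|A∩B|. Polytomies simply contribute fewer splits; branch
lengths are parsed but ignored (the pipeline is topology-only). RF is
reported unnormalized (raw split count); `normalize=True` divides by the
maximum 2(n−3). Duplicate topologies are retained, producing legitimate
zero off-diagonal distances that every downstream stage must — and does —
tolerate.

The matrix is stored dense: even ~7,000 trees give ~50M entries
(~400 MB), acceptable in memory, and no sparse path is provided.

## Stress functions

All four stresses sum over unordered pairs i &lt; j of the discrepancy
between the input dissimilarity δᵢⱼ and the embedded Euclidean distance
dᵢⱼ; the definitions are the canonical published forms (normalized stress
divides by Σδ², Kruskal-1 by Σd² under a square root, Sammon/NLM weights
by 1/δ and its normalizer, CCA applies an output-distance step weight).
Pairs with δ = 0 (duplicate topologies) are excluded from the NLM sums to
avoid division by zero and are kept, with their natural weight, in the
other three — they exert coincident-placement pressure.

The CCA neighborhood radius λ decays geometrically per optimizer sweep
from λ₀ (default: the data diameter max δ) to λ_end (default 0.05·max δ).
The weight is the Demartines–Hérault step function of the *embedded*
distance; a smooth decay weight would be an easy substitution (the weight
enters the code in exactly two places) but the step form is the default.
Because the weight changes with λ, raw CCA stress values are not
comparable across runs with different schedules; cross-method comparison
must go through the rank-based diagnostics below.

Gradients are analytic. For CCA the step weight is held piecewise
constant (the subgradient at the discontinuity takes the interior
branch); coincident points get a zero subgradient. Finite-difference
agreement is verified to better than 1e-5 in the test suite.

## Optimizers

Fourteen of the sixteen stress×optimizer combinations are admissible:
majorization and Gauss–Seidel–Newton are not paired with CCA, and SGD
with Kruskal-1 is replaced by Linear Iteration. The exclusions are
enforced as given rather than re-derived. Every pairing runs from
multiple uniform-random starts (coordinates i.i.d. on [0, max δ];
default 10 restarts) and reports per-restart final stresses, their mean
and standard error, and the best run. Convergence, where applicable, is
a relative full-stress change below `tol` (default 1e-6) for 10
consecutive sweeps — a criterion chosen to be robust to SGD noise.

* **Majorization (SMACOF).** Each sweep applies the Guttman transform,
  the exact minimizer of the quadratic majorizer of the weighted
  squared-error stress (weights 1 for normalized/Kruskal-1, 1/δ for NLM,
  with a pseudo-inverse of the weight Laplacian computed once). The
  recorded trace is that majorized objective, which is guaranteed
  monotone non-increasing; for Kruskal-1 — which SMACOF does not majorize
  directly — the Kruskal-1 value is evaluated on the final configuration.
* **Gauss–Seidel–Newton.** Cycles point-by-point, taking a damped Newton
  step per point from the analytic gradient and a positive Gauss–Newton
  diagonal curvature estimate; a step that raises the stress is halved up
  to 10 times, non-positive curvature falls back to a gradient step, and
  single-point stress changes are evaluated incrementally in O(N).
* **SGD.** For normalized/NLM stress, each sweep visits all pairs in
  seeded random order and moves both endpoints along the pair residual
  with step α_t = α₀/(1 + t/τ) (α₀ = 0.2, τ = 50); NLM pairs carry the
  1/δ weight, mean-normalized. Per-pair moves are trust-region capped at
  half the current pair separation because the Sammon weights are
  unbounded. For CCA each sweep visits all pivot points in random order
  and moves every within-λ neighbor of the pivot (the Demartines–Hérault
  update); λ and α decay per sweep and the run executes its full sweep
  budget, since CCA stress values at different λ are not comparable for
  an early-stopping rule.
* **MCMC simulated annealing.** Metropolis over single-point Gaussian
  proposals with geometric cooling (factor 0.99/sweep), returning the
  best state visited (for CCA: the best state after λ has finished
  decaying). Two calibrations matter and are defaults rather than
  constants: the start temperature is the median |Δstress| of 50 probe
  proposals (different stresses change by orders-of-magnitude different
  amounts per move — a fraction of the total stress either freezes or
  boils the chain), and the proposal width is 5% of the coordinate range
  scaled by max(√(T/T₀), 0.02) so the walk can still refine once only
  tiny moves are accepted.
* **Linear Iteration.** Fixed-step steepest descent on Kruskal-1
  (X ← X − η∇S, η = 0.05 of the data diameter, no line search, default
  3000 sweeps). Its trace is not guaranteed monotone and the method is
  retained precisely as the weak baseline it is. Divergence is detected
  both by stress blow-up and by coordinate spread exceeding 10× the data
  diameter — the latter matters because Kruskal-1 saturates near 1 as
  distances blow up, so runaway steps never show as stress divergence.

Determinism: identical (matrix, specs, seed) reproduces identical
embeddings bit-for-bit on all optimizers; restart seeds are
base_seed + i.

## Intrinsic dimensionality

* **Correlation dimension**: least-squares slope of log C(r) on log r
  over grid radii with 0 &lt; C(r) &lt; 1, where C(r) is the fraction of
  pairs closer than r. The default grid takes 20 quantiles of the
  distinct positive distances between the 0.5th and 20th percentile —
  the small-radius scaling region; at larger radii boundary saturation
  biases the slope low. RF distances are integers, so C(r) is a step
  function: for tightly clustered tree sets the small-radius band can be
  dominated by within-cluster steps and the estimate should be read with
  the grid in hand (the grid is caller-overridable everywhere).
* **Maximum likelihood (Levina–Bickel)**: inverse mean log-ratio of the
  k-th to j-th nearest-neighbor distances, averaged over points and over
  k ∈ [6, 12] (the k-range recommended by its authors; exposed). Zero
  neighbor distances (duplicates) are excluded with per-point guards.
* **Nearest neighbor (Pettis et al.)**: slope of log k against the log
  mean k-NN distance, iterated with the Gamma-function correction
  G(d,k) = k^{1/d}Γ(k)/Γ(k+1/d) until the estimate moves by &lt; 1e-3.
  Both the raw slope and the iterated value are available; the iterated
  value is the headline.
* **Stress vs dimension**: best final stress of a chosen admissible
  pairing (default CCA+SGD) at each target dimension. The "inspection"
  dimension is operationalized as the smallest dimension whose stress is
  within 5% of the stress at the largest dimension probed — but the raw
  curve is always emitted, because reading the elbow is ultimately a
  judgment call.

Neighbor structures break rank ties by point index, deterministically —
ties are frequent with integer RF distances and silent nondeterminism
here would leak into every rank-based diagnostic.

## Embedding diagnostics and replicate comparison

Trustworthiness and continuity use the standard rank-based forms with
k default 5 (reported over k ∈ {1, 5, 10, 20}); the two are exact duals
under exchange of the input and embedded spaces, which the tests
exploit. 1NN is nearest-neighbor partition-label agreement, reported for
the embedding alongside the same statistic on the input matrix as the
attainable ceiling; with L balanced random labels its chance level is
1/L.

Ordinary Procrustes aligns two configurations over translation,
orthogonal transforms (reflections included) and scale; the residual is
the aligned sum of squared deviations divided by the centered reference's
total sum of squares, so it lies in [0, 1] and is symmetric after
normalization. Replicate runs are declared non-equivalent when their
median residual to the other runs exceeds Q3 + 1.5·IQR of all pairwise
residuals — an operationalization of "very large relative to the others".
The rule needs the stray runs to be a minority of pairs; with only two
runs it is undefined and both are reported equivalent with a warning.

## Convex hulls

Outlier pruning interprets the variance threshold τ as a *relative* drop
(fraction of the current variance of within-group pairwise distances): an
absolute reading would make the default τ = 0.01 depend on the distance
scale. The absolute reading and a centroid-distance variant remain
available behind flags. Pruning is greedy one-at-a-time (largest drop
first, ties to the lowest index), which matches the iterative phrasing
and is deterministic; it is idempotent by construction. Note the rule's
sample-size sensitivity: each point participates in an O(1/N) share of
pairs, so at small N (tens of points) a 1% relative drop is easy to
exceed and pruning can cascade until the 3-point floor — τ should be
raised for small groups.

Hulls are computed with Qhull (scipy); rank-deficient groups fall back
to a hull in the spanned affine subspace and are flagged degenerate, as
are groups of fewer than 3 points. Separation translates each group
rigidly along the direction from the global centroid to the group
centroid; shape and within-group distances are preserved to float
roundoff (translation in floating point perturbs coordinate differences
at the last ulp, so "exact" here means ~1e-16 relative). Rendering is
static matplotlib (2D edges / 3D translucent facets) plus a JSON summary
of retained/removed indices, facets and centroids.

## Synthetic data

The generator reproduces the *distributional shape* of multi-partition
bootstrap tree sets without any tree inference: each partition has a
center topology drawn uniformly at random (sequential random leaf
attachment, so each of the (2n−5)!! topologies is equally likely), and
member trees apply a Poisson number of random NNI moves to the center,
with mean nni_scale/L_g for partition-length proxy L_g. The default
nni_scale = 200 with lengths in the few-hundreds-to-few-thousands range
(the scale of real mitochondrial gene partitions) spans ~2 down to ~0.1
expected moves per tree, giving the shorter-partition-wider-cluster
trend real bootstrap sets exhibit. The "null" mode shares one center
across partitions, mimicking a shuffled-columns control in which
partitions differ only by sampling error.

What this does *not* emulate: character resampling, ML tree search and
its failure modes, branch lengths, or any correlation between cluster
shape and tree shape. Passing tests on these fixtures show the distance,
embedding, dimensionality and hull machinery behave correctly on data
with the right cluster geometry — not that any biological conclusion
about a particular alignment would be reproduced.

Manifold samples (segment, square, cube, Gaussian-d, swiss roll, unit
scale, optionally rotated into a higher ambient dimension) provide
ground-truth intrinsic dimensions for calibrating the estimators.

## Problem sizes and defaults used in the checks

The automated checks run at desk scale, chosen once: stress/optimizer
recovery on 50 points from known 2D coordinates (3 restarts per
pairing); dimensionality recovery on 1000-point manifolds; the
end-to-end landscape on 5 partitions × 100 trees over 20 taxa (N = 500),
CCA+SGD with 3 restarts against Kruskal-1+Linear-Iteration with 2
restarts and a 1500-sweep budget; the partition-length trend on 10
partitions × 30 trees over 16 taxa. The multi-restart default for
production use remains 10.

## Known limitations

* Only the RF metric is built in; other tree distances (geodesic,
  quartet, SPR, branch-score, matching) must be computed externally and
  supplied as matrices.
* All-pairs O(N²) memory and time: no landmark/Nyström approximations,
  no parallelism.
* The MCMC and SGD hyperparameter defaults are calibrated on the
  recovery suite (exactly-embeddable instances and clustered RF
  landscapes); unusually scaled or heavy-tailed distance matrices may
  need retuning via the exposed parameters.
* Correlation dimension on integer-valued (RF) matrices is sensitive to
  the radius grid, as discussed above.
* Hull rendering is static; there is no interactive viewer.
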