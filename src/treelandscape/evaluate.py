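r"""Goodness-of-fit diagnostics for embeddings and replicate-run comparison.

Raw stress values from different cost functions cannot be compared, so
embeddings are scored with rank-based measures against the original
dissimilarities:

* **Trustworthiness** penalizes spurious neighbors — points that appear
  among a point's k nearest in the embedding but are not among its k
  nearest in the input distances:

  T(k) = 1 - 2 / (N k (2N - 3k - 1)) sum_i sum_{j in U_k(i)} (r(i,j) - k)

  where r(i,j) is j's rank in i's input-distance ordering.
* **Continuity** is the same form with the two spaces swapped: it
  penalizes true neighbors the embedding loses (e.g. by tearing a
  cluster apart).
* **1NN** is nearest-neighbor partition-label agreement: the fraction of
  points whose nearest neighbor shares their partition label.  Computed
  on the embedding, with the same statistic on the input distances as
  the attainable ceiling.

Replicate embeddings from different random starts are compared with
ordinary Procrustes analysis (translation, orthogonal transform
including reflection, and scale); runs whose residuals are very large
relative to the others are flagged non-equivalent.

Rank ties — frequent with integer RF distances — are broken by point
index, deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dimension import NeighborStructure
from .stress import embedded_distances

__all__ = [
    "FitReport",
    "ProcrustesResult",
    "trustworthiness",
    "continuity",
    "one_nn",
    "fit_report",
    "procrustes",
    "equivalence_classes",
]


def _as_delta(delta):
    return np.asarray(getattr(delta, "delta", delta), dtype=float)


def _as_distmat(space):
    """Accept either a coordinate matrix (N x p) or a distance matrix (N x N)."""
    a = np.asarray(getattr(space, "delta", getattr(space, "X", space)), dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D array")
    if a.shape[0] == a.shape[1] and np.allclose(a, a.T) and np.all(np.diag(a) == 0):
        return a
    return embedded_distances(a)


@dataclass
class FitReport:
    one_nn: float
    one_nn_ceiling: float
    continuity_k: dict
    trustworthiness_k: dict
    k_default: int = 5

    def to_dict(self):
        return {
            "one_nn": self.one_nn,
            "one_nn_ceiling": self.one_nn_ceiling,
            "continuity_k": {int(k): float(v) for k, v in self.continuity_k.items()},
            "trustworthiness_k": {int(k): float(v) for k, v in self.trustworthiness_k.items()},
            "k_default": self.k_default,
        }


@dataclass
class ProcrustesResult:
    residual: float
    scale: float
    rotation: np.ndarray
    translation: np.ndarray


def _rank_matrix(dist):
    return NeighborStructure.from_distances(dist, k_max=1).rank


def _rank_penalty(d_true, d_emb, k):
    """sum_i sum_{j in U_k(i)} (rank_true(i,j) - k) for the trustworthiness form."""
    n = d_true.shape[0]
    ns_true = NeighborStructure.from_distances(d_true)
    ns_emb = NeighborStructure.from_distances(d_emb)
    total = 0
    for i in range(n):
        true_k = set(ns_true.order[i, :k])
        pen = 0
        for j in ns_emb.order[i, :k]:
            if j not in true_k:
                pen += ns_true.rank[i, j] - k
        total += pen
    return total


def _tc_norm(n, k):
    return 2.0 / (n * k * (2 * n - 3 * k - 1))


def trustworthiness(delta, X, k=5):
    """1 is perfect; spurious embedding neighbors reduce it (see module docs)."""
    d_true = _as_delta(delta)
    n = d_true.shape[0]
    if not 1 <= k < n / 2:
        raise ValueError(f"need 1 <= k < N/2 = {n / 2}")
    d_emb = _as_distmat(X)
    return float(1.0 - _tc_norm(n, k) * _rank_penalty(d_true, d_emb, k))


def continuity(delta, X, k=5):
    """1 is perfect; input-space neighbors missing from the embedding reduce it."""
    d_true = _as_delta(delta)
    n = d_true.shape[0]
    if not 1 <= k < n / 2:
        raise ValueError(f"need 1 <= k < N/2 = {n / 2}")
    d_emb = _as_distmat(X)
    return float(1.0 - _tc_norm(n, k) * _rank_penalty(d_emb, d_true, k))


def one_nn(space, labels):
    """Fraction of points whose nearest neighbor shares their partition label.

    ``space`` may be an embedding (N x p coordinates) or a distance
    matrix; ties are broken toward the lowest index.
    """
    d = _as_distmat(space).copy()
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("1NN agreement is degenerate with a single partition label")
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)  # first minimum = lowest index on ties
    return float(np.mean(labels[nn] == labels))


def fit_report(delta, X, labels, ks=(1, 5, 10, 20), k_default=5):
    """Bundle 1NN (embedding + input-space ceiling) and T/C over several k."""
    d_true = _as_delta(delta)
    n = d_true.shape[0]
    ks = [k for k in ks if 1 <= k < n / 2]
    return FitReport(
        one_nn=one_nn(X, labels),
        one_nn_ceiling=one_nn(d_true, labels),
        continuity_k={k: continuity(d_true, X, k) for k in ks},
        trustworthiness_k={k: trustworthiness(d_true, X, k) for k in ks},
        k_default=k_default,
    )


def procrustes(X_ref, X_other):
    """Ordinary Procrustes: align X_other to X_ref over translation,
    orthogonal transform (reflections allowed) and scale.

    The residual is the sum of squared deviations after alignment divided
    by the total sum of squares of the centered reference, so it lies in
    [0, 1] and is 0 for exact similarity copies.
    """
    A = np.asarray(X_ref, dtype=float)
    B = np.asarray(X_other, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - mu_a, B - mu_b
    ssa = np.sum(A0**2)
    ssb = np.sum(B0**2)
    if ssa <= 0 or ssb <= 0:
        raise ValueError("degenerate configuration: all points coincident")
    U, s, Vt = np.linalg.svd(B0.T @ A0)
    Q = U @ Vt  # orthogonal, reflections permitted
    scale = np.sum(s) / ssb
    resid = np.sum((A0 - scale * (B0 @ Q)) ** 2) / ssa
    translation = mu_a - scale * (mu_b @ Q)
    return ProcrustesResult(residual=float(max(resid, 0.0)), scale=float(scale),
                            rotation=Q, translation=translation)


def _residual_matrix(runs):
    X = [getattr(r, "X", r) for r in runs]
    m = len(X)
    R = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r = procrustes(X[i], X[j]).residual
            R[i, j] = R[j, i] = r
    return R


def equivalence_classes(batch):
    """Partition replicate runs into Procrustes-equivalent groups.

    A run is flagged non-equivalent when its median residual to the other
    runs exceeds Q3 + 1.5 IQR of all pairwise residuals; the remaining
    (majority) runs form the equivalent class.  With two runs the outlier
    rule is undefined and both are reported equivalent with a warning.

    Returns (classes, residual_matrix) where classes is a list of lists
    of run indices, the majority class first.
    """
    runs = getattr(batch, "runs", batch)
    m = len(runs)
    if m < 2:
        raise ValueError("need at least 2 runs to compare")
    R = _residual_matrix(runs)
    if m == 2:
        warnings.warn("outlier rule undefined for 2 runs; reporting one class")
        return [[0, 1]], R
    iu = np.triu_indices(m, k=1)
    vals = R[iu]
    q1, q3 = np.percentile(vals, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    med = np.array([np.median(np.delete(R[i], i)) for i in range(m)])
    outliers = [i for i in range(m) if med[i] > cutoff]
    majority = [i for i in range(m) if i not in outliers]
    classes = [majority] if majority else []
    classes += [[i] for i in outliers]
    return classes, R
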