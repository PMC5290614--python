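r"""NLDR stress (cost) functions and their gradients.

An embedding places the N trees at coordinates X (N x p) so that the
Euclidean distances d_ij between rows track the input dissimilarities
delta_ij.  Four classical stress functions measure the discrepancy, all
summed over unordered pairs i < j:

* Normalized stress:   sum (delta - d)^2 / sum delta^2
* Kruskal-1 stress:    sqrt( sum (delta - d)^2 / sum d^2 )
* Sammon / NLM stress: (1 / sum' delta) * sum' (delta - d)^2 / delta,
  where sum' skips delta = 0 pairs (duplicate topologies)
* CCA stress:          sum (delta - d)^2 * F(d, lambda), with the step
  weight F(d, lambda) = 1 if d <= lambda else 0.

The CCA weight depends on the *output* distance d, which is what lets
the optimizer "tear" the distance manifold: pairs the embedding has
pushed beyond the neighborhood radius lambda stop contributing, so close
pairs can be drawn together without also dragging distant ones.  lambda
shrinks geometrically over the optimization, from the data diameter down
to a small fraction of it.

Gradients are analytic; for CCA the step weight is held piecewise
constant (the subgradient at the discontinuity takes the interior
branch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "STRESS_NAMES",
    "StressSpec",
    "embedded_distances",
    "stress_normalized",
    "stress_kruskal1",
    "stress_nlm",
    "stress_cca",
    "stress_value",
    "stress_gradient",
]

STRESS_NAMES = ("normalized", "kruskal1", "nlm", "cca")


@dataclass
class StressSpec:
    """Selects a stress function and carries the CCA neighborhood schedule.

    ``cca_lambda0``/``cca_lambda_end`` default to max(delta) and
    0.05 * max(delta) at run time; lambda decays geometrically per
    optimizer sweep between them.
    """

    name: str = "normalized"
    cca_lambda0: float | None = None
    cca_lambda_end: float | None = None
    eps: float = 1e-12

    def __post_init__(self):
        if self.name not in STRESS_NAMES:
            raise ValueError(f"unknown stress {self.name!r}; choose from {STRESS_NAMES}")
        if self.cca_lambda0 is not None and self.cca_lambda_end is not None:
            if not (self.cca_lambda0 >= self.cca_lambda_end > 0):
                raise ValueError("need lambda0 >= lambda_end > 0")

    def lambda_schedule(self, delta_max, n_sweeps):
        """Geometric lambda decay over n_sweeps sweeps (CCA only)."""
        lam0 = self.cca_lambda0 if self.cca_lambda0 is not None else float(delta_max)
        lam_end = (self.cca_lambda_end if self.cca_lambda_end is not None
                   else 0.05 * float(delta_max))
        if not lam0 >= lam_end > 0:
            raise ValueError("need lambda0 >= lambda_end > 0")
        if n_sweeps <= 1:
            return np.array([lam_end])
        ratio = (lam_end / lam0) ** (1.0 / (n_sweeps - 1))
        return lam0 * ratio ** np.arange(n_sweeps)


def embedded_distances(X):
    """Pairwise Euclidean distance matrix of the embedding rows."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding coordinates must be finite")
    return squareform(pdist(X))


def _pairs(delta, d):
    delta = np.asarray(delta, dtype=float)
    d = np.asarray(d, dtype=float)
    if delta.shape != d.shape:
        raise ValueError(f"shape mismatch: {delta.shape} vs {d.shape}")
    iu = np.triu_indices(delta.shape[0], k=1)
    return delta[iu], d[iu]


def stress_normalized(delta, d):
    dl, dd = _pairs(delta, d)
    denom = np.sum(dl**2)
    if denom == 0:
        raise ValueError("all input distances are zero: normalized stress undefined")
    return float(np.sum((dl - dd) ** 2) / denom)


def stress_kruskal1(delta, d):
    dl, dd = _pairs(delta, d)
    denom = np.sum(dd**2)
    if denom == 0:
        raise ValueError("all embedded distances are zero: Kruskal-1 stress undefined")
    return float(np.sqrt(np.sum((dl - dd) ** 2) / denom))


def stress_nlm(delta, d):
    dl, dd = _pairs(delta, d)
    mask = dl > 0
    if not np.any(mask):
        raise ValueError("all input distances are zero: NLM stress undefined")
    dl, dd = dl[mask], dd[mask]
    return float(np.sum((dl - dd) ** 2 / dl) / np.sum(dl))


def stress_cca(delta, d, lam):
    if lam <= 0:
        raise ValueError("CCA neighborhood radius lambda must be positive")
    dl, dd = _pairs(delta, d)
    w = dd <= lam
    return float(np.sum((dl - dd) ** 2 * w))


def stress_value(spec, delta, X, lam=None):
    """Evaluate the stress named by ``spec`` at coordinates X."""
    d = embedded_distances(X)
    if spec.name == "normalized":
        return stress_normalized(delta, d)
    if spec.name == "kruskal1":
        return stress_kruskal1(delta, d)
    if spec.name == "nlm":
        return stress_nlm(delta, d)
    if lam is None:
        raise ValueError("CCA stress needs the current lambda")
    return stress_cca(delta, d, lam)


def _gprime(spec, delta, d, lam):
    """dStress/dd_ij per unordered pair, as a full symmetric matrix."""
    n = delta.shape[0]
    iu = np.triu_indices(n, k=1)
    dl, dd = delta[iu], d[iu]
    if spec.name == "normalized":
        gp = -2.0 * (dl - dd) / np.sum(dl**2)
    elif spec.name == "kruskal1":
        A = np.sum((dl - dd) ** 2)
        B = np.sum(dd**2)
        S = np.sqrt(A / B)
        if S < spec.eps:
            gp = np.zeros_like(dl)
        else:
            gp = (-(dl - dd) * B - A * dd) / (S * B**2)
    elif spec.name == "nlm":
        mask = dl > 0
        gp = np.zeros_like(dl)
        gp[mask] = -2.0 * (dl[mask] - dd[mask]) / (dl[mask] * np.sum(dl[mask]))
    elif spec.name == "cca":
        gp = -2.0 * (dl - dd) * (dd <= lam)
    else:  # pragma: no cover - guarded by StressSpec
        raise ValueError(spec.name)
    G = np.zeros((n, n))
    G[iu] = gp
    return G + G.T


def stress_gradient(spec, delta, X, lam=None):
    """Analytic gradient dStress/dX, shape N x p.

    Uses grad_i = sum_j c_ij (x_i - x_j) with c_ij = g'(d_ij) / d_ij;
    coincident points (d = 0) get a zero subgradient.
    """
    X = np.asarray(X, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if spec.name == "cca" and lam is None:
        raise ValueError("CCA gradient needs the current lambda")
    d = embedded_distances(X)
    G = _gprime(spec, delta, d, lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(d > spec.eps, G / np.where(d > spec.eps, d, 1.0), 0.0)
    return C.sum(axis=1)[:, None] * X - C @ X
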