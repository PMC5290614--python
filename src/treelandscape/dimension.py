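r"""Intrinsic dimensionality estimation for distance matrices.

Whether a 2D or 3D tree landscape can represent a set of tree-to-tree
distances without serious distortion depends on the intrinsic
dimensionality of those distances.  Four routes are provided:

* **Correlation dimension** — slope of log C(r) against log r, where
  C(r) = 2/(N(N-1)) #{i<j : delta_ij < r} is the fraction of pairs
  closer than r.
* **Maximum-likelihood (Levina-Bickel)** — inverse mean log ratio of
  k-th to j-th nearest-neighbor distances, averaged over points and a
  k-range.
* **Nearest-neighbor (Pettis et al.)** — slope of log k against the log
  mean k-NN distance, iteratively refined with the Gamma-function bias
  correction G(d, k) = k^{1/d} Gamma(k) / Gamma(k + 1/d).
* **Stress-vs-dimension curve** — the best final NLDR stress as a
  function of the target dimension; the elbow where added dimensions
  stop helping indicates how many are needed.

RF distances are integers, so C(r) is a step function; the default
radius grid therefore uses quantiles of the observed distinct distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import linregress

from .optimize import run_batch

__all__ = [
    "NeighborStructure",
    "DimReport",
    "correlation_dimension",
    "ml_dimension",
    "nn_dimension",
    "stress_vs_dimension",
    "estimate_dimensionality",
    "default_radius_grid",
]


def _as_delta(delta):
    return np.asarray(getattr(delta, "delta", delta), dtype=float)


@dataclass
class NeighborStructure:
    """Per-point neighbor distances and ranks derived from a distance matrix.

    ``T[i, k-1]`` is the distance from point i to its k-th nearest
    neighbor (self excluded; ties broken by point index), and
    ``rank[i, j]`` is the rank (1..N-1) of j in i's distance ordering.
    """

    T: np.ndarray
    rank: np.ndarray
    order: np.ndarray

    @classmethod
    def from_distances(cls, delta, k_max=None):
        d = _as_delta(delta)
        n = d.shape[0]
        if k_max is None:
            k_max = n - 1
        k_max = min(k_max, n - 1)
        # deterministic tie-break by index: lexsort on (index, distance)
        idx = np.arange(n)
        order = np.empty((n, n - 1), dtype=int)
        rank = np.zeros((n, n), dtype=int)
        for i in range(n):
            di = d[i].copy()
            di[i] = np.inf
            o = np.lexsort((idx, di))[:-1]  # drop self (at the end)
            order[i] = o
            rank[i, o] = np.arange(1, n)
        T = np.take_along_axis(d, order[:, :k_max], axis=1)
        return cls(T=T, rank=rank, order=order)


@dataclass
class DimReport:
    nn_estimate: float
    cor_estimate: float
    ml_estimate: float
    stress_curve: list = field(default_factory=list)
    inspection_dim: int | None = None

    def to_dict(self):
        return {
            "nn_estimate": self.nn_estimate,
            "cor_estimate": self.cor_estimate,
            "ml_estimate": self.ml_estimate,
            "stress_curve": [[int(k), float(v)] for k, v in self.stress_curve],
            "inspection_dim": self.inspection_dim,
        }


def default_radius_grid(delta, n_points=20, lo=0.005, hi=0.2):
    """Quantile grid over the distinct positive distances.

    The default band covers the small-radius scaling region where
    log C(r) is linear in log r; at large radii boundary saturation
    (C -> 1) flattens the slope and biases the estimate low.
    """
    d = _as_delta(delta)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    vals = np.unique(vals[vals > 0])
    if len(vals) < 3:
        raise ValueError("too few distinct positive distances for a radius grid")
    qs = np.linspace(lo, hi, n_points)
    return np.unique(np.quantile(vals, qs))


def correlation_dimension(delta, r_grid=None):
    """Slope of log C(r) on log r over grid points with 0 < C(r) < 1."""
    d = _as_delta(delta)
    n = d.shape[0]
    if r_grid is None:
        r_grid = default_radius_grid(d)
    r_grid = np.asarray(r_grid, dtype=float)
    iu = np.triu_indices(n, k=1)
    pd = d[iu]
    npairs = len(pd)
    log_r, log_c = [], []
    for r in r_grid:
        if r <= 0:
            continue
        c = np.count_nonzero(pd < r) / npairs
        if 0 < c < 1:
            log_r.append(np.log(r))
            log_c.append(np.log(c))
    if len(log_r) < 3:
        raise ValueError(
            "fewer than 3 usable radii with 0 < C(r) < 1; widen the radius grid"
        )
    res = linregress(log_r, log_c)
    return float(res.slope)


def ml_dimension(ns, k1=6, k2=12):
    """Levina-Bickel maximum-likelihood estimator.

    m_k(i) = [ (1/(k-1)) sum_{j<k} log(T_ik / T_ij) ]^{-1}, averaged over
    points i and k in [k1, k2].  Zero neighbor distances (duplicate
    points) are excluded from the inner sum; points whose k-th neighbor
    is at distance zero are skipped for that k.
    """
    T = ns.T
    n, k_max = T.shape
    if not (2 <= k1 < k2 <= k_max):
        raise ValueError(f"need 2 <= k1 < k2 <= k_max={k_max}")
    est = []
    for k in range(k1, k2 + 1):
        tk = T[:, k - 1]
        vals = []
        for i in range(n):
            if tk[i] <= 0:
                continue
            tj = T[i, : k - 1]
            tj = tj[tj > 0]
            if len(tj) == 0:
                continue
            s = np.mean(np.log(tk[i] / tj))
            if s > 0:
                vals.append(1.0 / s)
        if vals:
            est.append(np.mean(vals))
    if not est:
        raise ValueError("no usable points: all neighbor distances are zero")
    return float(np.mean(est))


def _pettis_gd(d, ks):
    """log G(d, k) with G(d, k) = k^(1/d) Gamma(k) / Gamma(k + 1/d)."""
    return np.log(ks) / d + gammaln(ks) - gammaln(ks + 1.0 / d)


def nn_dimension(ns, k_max=10, tol=1e-3, max_iter=100, return_raw=False):
    """Pettis nearest-neighbor estimator.

    Fits log k against log of the mean k-NN distance r_k (slope = d),
    then iterates the fit with the Gamma-function bias correction
    G(d, k) applied to r_k until the estimate changes by < tol.
    """
    T = ns.T
    if k_max < 3 or k_max > T.shape[1]:
        raise ValueError(f"need 3 <= k_max <= {T.shape[1]}")
    ks = np.arange(1, k_max + 1, dtype=float)
    r_bar = T[:, :k_max].mean(axis=0)
    if np.any(r_bar <= 0) or np.allclose(r_bar, r_bar[0]):
        raise ValueError("degenerate neighbor distances: NN estimator undefined")
    log_k = np.log(ks)
    slope = linregress(np.log(r_bar), log_k).slope
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError("non-finite or non-positive raw NN slope")
    raw = float(slope)
    d_est = raw
    for _ in range(max_iter):
        corrected = np.log(r_bar) + _pettis_gd(d_est, ks)
        new = linregress(corrected, log_k).slope
        if not np.isfinite(new) or new <= 0:
            break
        if abs(new - d_est) < tol:
            d_est = new
            break
        d_est = new
    if return_raw:
        return float(d_est), raw
    return float(d_est)


def stress_vs_dimension(delta, dims, stress_name="cca", optimizer_name="sgd",
                        n_restarts=3, base_seed=0, stress_spec=None, opt_spec=None):
    """Best final stress of the given admissible pairing at each target dim."""
    if not dims:
        raise ValueError("dims must be non-empty")
    if any(p < 1 for p in dims):
        raise ValueError("all dims must be >= 1")
    curve = []
    for p in dims:
        batch = run_batch(delta, stress_name, optimizer_name, p=p,
                          n_restarts=n_restarts, base_seed=base_seed,
                          stress_spec=stress_spec, opt_spec=opt_spec)
        curve.append((int(p), float(batch.best.final_stress)))
    return curve


def inspection_dimension(curve, rel_tol=0.05):
    """Smallest dimension whose stress is within rel_tol of the last one.

    Operationalizes reading the elbow off the stress-vs-dimension curve;
    the raw curve should always be reported alongside this number.
    """
    curve = sorted(curve)
    floor = curve[-1][1]
    for p, s in curve:
        if s <= floor * (1 + rel_tol) + 1e-30:
            return int(p)
    return int(curve[-1][0])


def estimate_dimensionality(delta, dims=None, k1=6, k2=12, nn_k_max=10,
                            r_grid=None, stress_name="cca", optimizer_name="sgd",
                            n_restarts=3, base_seed=0, opt_spec=None):
    """All four estimates bundled into a :class:`DimReport`."""
    d = _as_delta(delta)
    ns = NeighborStructure.from_distances(d, k_max=max(k2, nn_k_max))
    cor = correlation_dimension(d, r_grid)
    ml = ml_dimension(ns, k1=k1, k2=k2)
    nn = nn_dimension(ns, k_max=nn_k_max)
    curve, insp = [], None
    if dims:
        curve = stress_vs_dimension(d, dims, stress_name, optimizer_name,
                                    n_restarts=n_restarts, base_seed=base_seed,
                                    opt_spec=opt_spec)
        insp = inspection_dimension(curve)
    return DimReport(nn_estimate=nn, cor_estimate=cor, ml_estimate=ml,
                     stress_curve=curve, inspection_dim=insp)
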