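"""Stress optimizers and the multi-restart embedding driver.

Five optimizers are provided — majorization (SMACOF), Gauss-Seidel-Newton,
stochastic gradient descent (SGD), MCMC simulated annealing, and Linear
Iteration (fixed-step steepest descent on Kruskal-1 stress) — combined
with the four stress functions into exactly 14 admissible pairings:

* majorization / Gauss-Seidel-Newton / MCMC with each of
  {normalized, kruskal1, nlm}            (9)
* SGD with {normalized, nlm}             (2)
* SGD and MCMC with cca                  (2)
* Linear Iteration with kruskal1         (1)

Majorization and Gauss-Seidel with CCA are excluded, and SGD with
Kruskal-1 is replaced by Linear Iteration.  NLDR is non-convex, so the
driver runs each pairing from multiple random starts (default 10) and
reports per-restart final stresses alongside the best embedding.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .stress import StressSpec, embedded_distances, stress_value

__all__ = [
    "OPTIMIZER_NAMES",
    "OptimizerSpec",
    "Embedding",
    "RunBatch",
    "InadmissiblePairError",
    "admissible_pairs",
    "initialize",
    "embed",
    "run_batch",
    "run_majorization",
    "run_gauss_seidel_newton",
    "run_sgd",
    "run_mcmc",
    "run_linear_iteration",
]

OPTIMIZER_NAMES = ("majorization", "gauss_seidel_newton", "sgd", "mcmc", "linear_iteration")

_PAIRS = (
    [("normalized", o) for o in ("majorization", "gauss_seidel_newton", "mcmc")]
    + [("kruskal1", o) for o in ("majorization", "gauss_seidel_newton", "mcmc")]
    + [("nlm", o) for o in ("majorization", "gauss_seidel_newton", "mcmc")]
    + [("normalized", "sgd"), ("nlm", "sgd")]
    + [("cca", "sgd"), ("cca", "mcmc")]
    + [("kruskal1", "linear_iteration")]
)


class InadmissiblePairError(ValueError):
    pass


def admissible_pairs():
    """The 14 admissible (stress, optimizer) pairings (of 16 possible).

    Majorization+CCA and Gauss-Seidel+CCA are excluded, and SGD with
    Kruskal-1 is replaced by Linear Iteration (fixed-step steepest
    descent).
    """
    return list(_PAIRS)


def _check_pair(stress_name, optimizer_name):
    if (stress_name, optimizer_name) not in _PAIRS:
        raise InadmissiblePairError(
            f"({stress_name}, {optimizer_name}) is not one of the 14 admissible "
            "stress/optimizer pairings: majorization+cca and "
            "gauss_seidel_newton+cca are excluded, and kruskal1+sgd is "
            "replaced by kruskal1+linear_iteration"
        )


@dataclass
class OptimizerSpec:
    """Optimizer hyperparameters (all CLI-exposed).

    ``tol`` is a relative full-stress change; a run stops once the change
    stays below it for ``patience`` consecutive sweeps.  The SGD step
    follows alpha_t = alpha0 / (1 + t / sgd_tau).  MCMC starts at
    temperature T0 (default: initial stress / N), cools geometrically by
    ``cooling`` per sweep, and proposes single-point Gaussian moves with
    sigma = ``sigma_frac`` of the current coordinate range.  Linear
    Iteration uses the fixed step ``eta``.
    """

    name: str = "majorization"
    max_sweeps: int = 1000
    tol: float = 1e-6
    patience: int = 10
    alpha0: float = 0.2
    sgd_tau: float = 50.0
    T0: float | None = None
    cooling: float = 0.99
    sigma_frac: float = 0.05
    eta: float = 0.05

    def __post_init__(self):
        if self.name not in OPTIMIZER_NAMES:
            raise ValueError(f"unknown optimizer {self.name!r}")
        if self.max_sweeps < 1 or self.tol <= 0:
            raise ValueError("need max_sweeps >= 1 and tol > 0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class Embedding:
    """An embedding plus its provenance (stress, optimizer, seed, stress value)."""

    X: np.ndarray
    p: int
    stress_name: str
    optimizer_name: str
    seed: int
    final_stress: float
    runtime_seconds: float = 0.0
    n_sweeps: int = 0
    converged: bool = False
    trace: np.ndarray | None = None


@dataclass
class RunBatch:
    """Restart ensemble for one stress/optimizer pairing."""

    runs: list
    n_restarts: int
    seeds: list = field(default_factory=list)

    @property
    def final_stresses(self):
        return np.array([r.final_stress for r in self.runs])

    @property
    def best(self):
        return self.runs[int(np.argmin(self.final_stresses))]

    @property
    def mean_stress(self):
        return float(np.mean(self.final_stresses))

    @property
    def stderr_stress(self):
        s = self.final_stresses
        if len(s) < 2:
            return 0.0
        return float(np.std(s, ddof=1) / np.sqrt(len(s)))


def _as_delta(delta):
    d = getattr(delta, "delta", delta)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("delta must be a square matrix")
    return d


def initialize(delta, p, seed):
    """Random start: coordinates i.i.d. uniform on [0, max(delta)] per axis."""
    d = _as_delta(delta)
    if p < 1:
        raise ValueError("target dimension must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, float(d.max()), size=(d.shape[0], p))


def _condensed(delta):
    iu = np.triu_indices(delta.shape[0], k=1)
    return iu, delta[iu]


class _Converged:
    """Stop when the relative stress change stays below tol for `patience` sweeps."""

    def __init__(self, tol, patience):
        self.tol, self.patience = tol, patience
        self.prev = None
        self.count = 0

    def step(self, s):
        if self.prev is not None:
            denom = max(abs(self.prev), 1e-12)
            self.count = self.count + 1 if abs(s - self.prev) / denom < self.tol else 0
        self.prev = s
        return self.count >= self.patience


# ---------------------------------------------------------------------------
# incremental single-point stress bookkeeping (Gauss-Seidel-Newton, MCMC)

class _PairState:
    """Maintains d(X) and pair sums so moving one point costs O(N)."""

    def __init__(self, delta, X, stress_name, lam=None, eps=1e-12):
        self.delta = delta
        self.X = np.array(X, dtype=float)
        self.name = stress_name
        self.eps = eps
        self.D = embedded_distances(self.X)
        iu, dl = _condensed(delta)
        self.Sd2 = float(np.sum(dl**2))
        pos = dl > 0
        self.Sd = float(np.sum(dl[pos]))
        if self.Sd2 == 0:
            raise ValueError("degenerate input: all distances zero")
        self.lam = lam
        self._recompute_sums()

    def _recompute_sums(self):
        iu, dl = _condensed(self.delta)
        dd = self.D[iu]
        self.A = float(np.sum((dl - dd) ** 2))
        self.B = float(np.sum(dd**2))
        pos = dl > 0
        self.An = float(np.sum((dl[pos] - dd[pos]) ** 2 / dl[pos]))
        if self.lam is not None:
            self.Scca = float(np.sum((dl - dd) ** 2 * (dd <= self.lam)))

    def set_lambda(self, lam):
        self.lam = lam
        self._recompute_sums()

    def _stress_from(self, A, B, An, Scca):
        # incremental sums can drift slightly negative near a perfect fit
        if self.name == "normalized":
            return max(A, 0.0) / self.Sd2
        if self.name == "kruskal1":
            return np.sqrt(max(A, 0.0) / B) if B > 0 else np.inf
        if self.name == "nlm":
            return max(An, 0.0) / self.Sd
        return max(Scca, 0.0)

    def stress(self):
        return self._stress_from(self.A, self.B, self.An,
                                 getattr(self, "Scca", 0.0))

    def propose(self, i, xi_new):
        """Stress after moving point i to xi_new, without committing."""
        dn = np.sqrt(np.sum((self.X - xi_new) ** 2, axis=1))
        dn[i] = 0.0
        do = self.D[i]
        dl = self.delta[i]
        m = np.ones(len(dl), dtype=bool)
        m[i] = False
        dA = np.sum((dl[m] - dn[m]) ** 2 - (dl[m] - do[m]) ** 2)
        dB = np.sum(dn[m] ** 2 - do[m] ** 2)
        pos = m & (dl > 0)
        dAn = np.sum(((dl[pos] - dn[pos]) ** 2 - (dl[pos] - do[pos]) ** 2) / dl[pos])
        if self.lam is not None:
            dS = np.sum((dl[m] - dn[m]) ** 2 * (dn[m] <= self.lam)
                        - (dl[m] - do[m]) ** 2 * (do[m] <= self.lam))
            Scca = self.Scca + dS
        else:
            Scca = 0.0
        sums = (self.A + dA, self.B + dB, self.An + dAn, Scca)
        return self._stress_from(*sums), sums, dn

    def commit(self, i, xi_new, sums, dn):
        self.X[i] = xi_new
        self.D[i, :] = dn
        self.D[:, i] = dn
        self.A, self.B, self.An = sums[0], sums[1], sums[2]
        if self.lam is not None:
            self.Scca = sums[3]

    def point_gradient(self, i):
        """Gradient of the stress w.r.t. x_i, plus a positive diagonal
        curvature estimate (Gauss-Newton) per coordinate."""
        do = self.D[i]
        dl = self.delta[i]
        m = do > self.eps
        m[i] = False
        gp = np.zeros(len(dl))
        w = np.zeros(len(dl))
        if self.name == "normalized":
            gp[m] = -2.0 * (dl[m] - do[m]) / self.Sd2
            w[m] = 1.0 / self.Sd2
        elif self.name == "kruskal1":
            S = np.sqrt(self.A / self.B) if self.B > 0 else 0.0
            if S > self.eps:
                gp[m] = (-(dl[m] - do[m]) * self.B - self.A * do[m]) / (S * self.B**2)
                w[m] = 1.0 / (S * self.B)
            else:
                w[m] = 1.0 / max(self.B, self.eps)
        elif self.name == "nlm":
            mp = m & (dl > 0)
            gp[mp] = -2.0 * (dl[mp] - do[mp]) / (dl[mp] * self.Sd)
            w[mp] = 1.0 / (dl[mp] * self.Sd)
        else:  # cca
            mw = m & (do <= self.lam)
            gp[mw] = -2.0 * (dl[mw] - do[mw])
            w[mw] = 1.0
        c = np.where(m, gp / np.where(m, do, 1.0), 0.0)
        diff = self.X[i][None, :] - self.X  # N x p
        g = c @ diff
        h = (2.0 * w / np.where(m, do, 1.0) ** 2) @ diff**2
        return g, h


# ---------------------------------------------------------------------------
# optimizers

def run_majorization(delta, stress_spec, X0, opt_spec=None, record_trace=True):
    """SMACOF: each sweep applies the Guttman transform, the exact minimizer
    of the quadratic majorizer of the weighted squared-error stress
    (weights 1 for normalized/kruskal1, 1/delta for nlm).  The recorded
    trace is that majorized objective, which is guaranteed non-increasing;
    the named stress is evaluated on the final configuration.
    """
    delta = _as_delta(delta)
    opt_spec = opt_spec or OptimizerSpec(name="majorization")
    if stress_spec.name not in ("normalized", "kruskal1", "nlm"):
        _check_pair(stress_spec.name, "majorization")
    n = delta.shape[0]
    iu, dl = _condensed(delta)
    if np.sum(dl**2) == 0:
        raise ValueError("degenerate input: all distances zero")
    if stress_spec.name == "nlm":
        W = np.zeros_like(delta)
        nz = delta > 0
        W[nz] = 1.0 / delta[nz]
        np.fill_diagonal(W, 0.0)
        V = np.diag(W.sum(axis=1)) - W
        Vp = np.linalg.pinv(V)
    else:
        W = np.ones_like(delta)
        np.fill_diagonal(W, 0.0)
        Vp = None

    X = np.array(X0, dtype=float)
    trace = []
    conv = _Converged(opt_spec.tol, opt_spec.patience)
    sweeps = 0
    for sweeps in range(1, opt_spec.max_sweeps + 1):
        D = embedded_distances(X)
        sigma = float(np.sum(W[iu] * (dl - D[iu]) ** 2))
        trace.append(sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            Bmat = np.where(D > stress_spec.eps,
                            -W * delta / np.where(D > stress_spec.eps, D, 1.0), 0.0)
        np.fill_diagonal(Bmat, 0.0)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        BX = Bmat @ X
        X = BX / n if Vp is None else Vp @ BX
        if conv.step(sigma):
            break
    D = embedded_distances(X)
    trace.append(float(np.sum(W[iu] * (dl - D[iu]) ** 2)))
    final = stress_value(stress_spec, delta, X)
    return Embedding(X=X, p=X.shape[1], stress_name=stress_spec.name,
                     optimizer_name="majorization", seed=-1, final_stress=final,
                     n_sweeps=sweeps, converged=conv.count >= conv.patience,
                     trace=np.array(trace) if record_trace else None)


def run_gauss_seidel_newton(delta, stress_spec, X0, opt_spec=None):
    """Cyclic point-wise damped Newton descent.

    Each point's coordinates take a Newton step using the analytic
    gradient and a positive diagonal (Gauss-Newton) curvature estimate of
    the stress restricted to that point, applied in place; a step that
    increases the stress is halved up to 10 times, and non-positive
    curvature falls back to a gradient step.
    """
    delta = _as_delta(delta)
    opt_spec = opt_spec or OptimizerSpec(name="gauss_seidel_newton")
    _check_pair(stress_spec.name, "gauss_seidel_newton")
    st = _PairState(delta, X0, stress_spec.name, eps=stress_spec.eps)
    n = delta.shape[0]
    cur = st.stress()
    scale = float(delta.max())
    conv = _Converged(opt_spec.tol, opt_spec.patience)
    sweeps = 0
    for sweeps in range(1, opt_spec.max_sweeps + 1):
        if sweeps % 50 == 0:
            st._recompute_sums()
            cur = st.stress()
        for i in range(n):
            g, h = st.point_gradient(i)
            gnorm = np.linalg.norm(g)
            if gnorm < 1e-30:
                continue
            ok = h > stress_spec.eps
            step = np.where(ok, -g / np.where(ok, h, 1.0),
                            -g / gnorm * 0.1 * scale)
            for _ in range(11):
                s_new, sums, dn = st.propose(i, st.X[i] + step)
                if s_new < cur:
                    st.commit(i, st.X[i] + step, sums, dn)
                    cur = s_new
                    break
                step = step / 2.0
        if conv.step(cur):
            break
    return Embedding(X=st.X, p=st.X.shape[1], stress_name=stress_spec.name,
                     optimizer_name="gauss_seidel_newton", seed=-1,
                     final_stress=float(cur), n_sweeps=sweeps,
                     converged=conv.count >= conv.patience)


def run_sgd(delta, stress_spec, X0, opt_spec=None, rng=None):
    """Stochastic gradient descent.

    For normalized/nlm stress each sweep visits all pairs in seeded
    random order, stepping both endpoints down the pair's weighted
    residual (nlm pairs carry the Sammon 1/delta weight, mean-normalized;
    delta = 0 pairs are excluded for nlm).  For cca each sweep visits all
    pivot points in random order and moves their within-lambda neighbors
    (Demartines-Herault), with lambda decaying geometrically per sweep.
    Convergence is evaluated on the full stress each sweep.
    """
    delta = _as_delta(delta)
    opt_spec = opt_spec or OptimizerSpec(name="sgd")
    _check_pair(stress_spec.name, "sgd")
    rng = rng or np.random.default_rng(0)
    X = np.array(X0, dtype=float)
    n = delta.shape[0]
    conv = _Converged(opt_spec.tol, opt_spec.patience)

    if stress_spec.name == "cca":
        lam_arr = stress_spec.lambda_schedule(delta.max(), opt_spec.max_sweeps)
        cur = None
        for t in range(opt_spec.max_sweeps):
            alpha = opt_spec.alpha0 / (1.0 + t / opt_spec.sgd_tau)
            order = rng.permutation(n)
            _kernels.cca_pivot_sweep(X, delta, order, alpha, lam_arr[t])
        cur = stress_value(stress_spec, delta, X, lam=lam_arr[-1])
        return Embedding(X=X, p=X.shape[1], stress_name="cca", optimizer_name="sgd",
                         seed=-1, final_stress=float(cur),
                         n_sweeps=opt_spec.max_sweeps, converged=False)

    iu, dl = _condensed(delta)
    I, J = iu[0].astype(np.int64), iu[1].astype(np.int64)
    if stress_spec.name == "nlm":
        keep = dl > 0
        I, J, dl = I[keep], J[keep], dl[keep]
        w = (1.0 / dl) / np.mean(1.0 / dl)
    else:
        w = np.ones_like(dl)
    cur = stress_value(stress_spec, delta, X)
    sweeps = 0
    for sweeps in range(1, opt_spec.max_sweeps + 1):
        alpha = opt_spec.alpha0 / (1.0 + (sweeps - 1) / opt_spec.sgd_tau)
        order = rng.permutation(len(dl)).astype(np.int64)
        _kernels.sgd_pair_sweep(X, I, J, dl, w, order, alpha)
        cur = stress_value(stress_spec, delta, X)
        if conv.step(cur):
            break
    return Embedding(X=X, p=X.shape[1], stress_name=stress_spec.name,
                     optimizer_name="sgd", seed=-1, final_stress=float(cur),
                     n_sweeps=sweeps, converged=conv.count >= conv.patience)


def run_mcmc(delta, stress_spec, X0, opt_spec=None, rng=None):
    """Metropolis simulated annealing over single-point Gaussian moves.

    Proposals perturb one point; acceptance probability is
    min(1, exp(-dStress / T)); T cools geometrically per sweep.  The
    best-stress state ever visited is returned (for cca, the best state
    once lambda has finished decaying, since cca values at different
    lambda are not comparable).
    """
    delta = _as_delta(delta)
    opt_spec = opt_spec or OptimizerSpec(name="mcmc")
    _check_pair(stress_spec.name, "mcmc")
    rng = rng or np.random.default_rng(0)
    n = delta.shape[0]
    is_cca = stress_spec.name == "cca"
    if is_cca:
        n_decay = max(1, int(0.8 * opt_spec.max_sweeps))
        lam_arr = np.concatenate([
            stress_spec.lambda_schedule(delta.max(), n_decay),
            np.full(opt_spec.max_sweeps - n_decay, 0.0),
        ])
        lam_arr[n_decay:] = lam_arr[n_decay - 1]
        st = _PairState(delta, X0, "cca", lam=lam_arr[0], eps=stress_spec.eps)
    else:
        st = _PairState(delta, X0, stress_spec.name, eps=stress_spec.eps)
    cur = st.stress()
    if opt_spec.T0 is not None:
        T = opt_spec.T0
    else:
        # calibrate the start temperature to the scale of a typical
        # single-point move: stresses differ by orders of magnitude in
        # how a move changes them (e.g. the square root in Kruskal-1),
        # so a fixed fraction of the stress either freezes or boils
        span0 = float(np.max(st.X.max(axis=0) - st.X.min(axis=0)))
        probes = []
        for _ in range(50):
            i = int(rng.integers(0, n))
            xi = st.X[i] + opt_spec.sigma_frac * span0 * rng.standard_normal(st.X.shape[1])
            s_new, _, _ = st.propose(i, xi)
            probes.append(abs(s_new - cur))
        T = float(np.median(probes))
        if T <= 0:
            T = cur / n
    T = max(T, 1e-300)
    T_init = T
    best = np.inf
    bestX = st.X.copy()
    track_best = not is_cca
    conv = _Converged(opt_spec.tol, opt_spec.patience)
    p = st.X.shape[1]
    sweeps = 0
    for sweeps in range(1, opt_spec.max_sweeps + 1):
        if is_cca:
            lam = lam_arr[sweeps - 1]
            if lam != st.lam:
                st.set_lambda(lam)
                cur = st.stress()
            track_best = sweeps - 1 >= n_decay - 1
        if sweeps % 50 == 0:
            st._recompute_sums()
            cur = st.stress()
        rng_pts = rng.integers(0, n, size=n)
        span = float(np.max(st.X.max(axis=0) - st.X.min(axis=0)))
        # proposals shrink with the annealing temperature so the walk can
        # still refine the configuration once only tiny moves are accepted
        anneal = max(np.sqrt(T / T_init), 0.02)
        sigma = max(opt_spec.sigma_frac * span * anneal, 1e-12)
        noise = rng.standard_normal((n, p)) * sigma
        u = rng.random(n)
        for k in range(n):
            i = int(rng_pts[k])
            xi_new = st.X[i] + noise[k]
            s_new, sums, dn = st.propose(i, xi_new)
            dS = s_new - cur
            if dS <= 0 or u[k] < np.exp(-dS / T):
                st.commit(i, xi_new, sums, dn)
                cur = s_new
                if track_best and cur < best:
                    best = cur
                    bestX = st.X.copy()
        T *= opt_spec.cooling
        if not is_cca and conv.step(cur):
            break
    if not np.isfinite(best):
        best, bestX = cur, st.X
    return Embedding(X=bestX, p=p, stress_name=stress_spec.name,
                     optimizer_name="mcmc", seed=-1, final_stress=float(best),
                     n_sweeps=sweeps, converged=conv.count >= conv.patience)


def run_linear_iteration(delta, stress_spec, X0, opt_spec=None, record_trace=False):
    """Fixed-step steepest descent on Kruskal-1 stress (Linear Iteration).

    X <- X - eta * grad(stress) with a constant step every sweep and no
    line search, so the stress trace is not guaranteed monotone.

    Divergence aborts with a diagnostic.  Because Kruskal-1 stress
    saturates near 1 as the embedded distances blow up, runaway steps
    show as coordinate spread exploding at saturated stress rather than
    as stress blow-up; both signatures are watched.
    """
    from .stress import stress_gradient

    delta = _as_delta(delta)
    opt_spec = opt_spec or OptimizerSpec(name="linear_iteration")
    if stress_spec.name != "kruskal1":
        _check_pair(stress_spec.name, "linear_iteration")
    X = np.array(X0, dtype=float)
    s0 = stress_value(stress_spec, delta, X)
    cur = s0
    conv = _Converged(opt_spec.tol, opt_spec.patience)
    trace = [s0]
    sweeps = 0
    # eta is specified relative to the data diameter so the fixed step is
    # meaningful across distance scales
    eta = opt_spec.eta * float(delta.max())
    diameter = float(delta.max())
    spread0 = float(np.max(X.max(axis=0) - X.min(axis=0)))
    for sweeps in range(1, opt_spec.max_sweeps + 1):
        g = stress_gradient(stress_spec, delta, X)
        X = X - eta * g
        cur = stress_value(stress_spec, delta, X)
        trace.append(cur)
        spread = float(np.max(X.max(axis=0) - X.min(axis=0)))
        if (not np.isfinite(cur) or cur > 1e6 * max(s0, 1e-30)
                or spread > 10.0 * max(spread0, diameter)):
            raise RuntimeError(
                f"linear iteration diverged (stress {cur:.3g} from {s0:.3g}, "
                f"coordinate spread {spread:.3g}); use a smaller fixed step eta"
            )
        if conv.step(cur):
            break
    return Embedding(X=X, p=X.shape[1], stress_name="kruskal1",
                     optimizer_name="linear_iteration", seed=-1,
                     final_stress=float(cur), n_sweeps=sweeps,
                     converged=conv.count >= conv.patience,
                     trace=np.array(trace) if record_trace else None)


# ---------------------------------------------------------------------------
# driver

def embed(delta, stress_name="normalized", optimizer_name="majorization", p=2,
          seed=0, stress_spec=None, opt_spec=None):
    """Run one seeded embedding for an admissible stress/optimizer pair."""
    _check_pair(stress_name, optimizer_name)
    delta = _as_delta(delta)
    sspec = stress_spec or StressSpec(name=stress_name)
    if sspec.name != stress_name:
        raise ValueError("stress_spec.name disagrees with stress_name")
    if opt_spec is not None:
        ospec = opt_spec
    elif optimizer_name == "linear_iteration":
        # the fixed-step descent has no line search and cheap sweeps;
        # it needs a larger budget to reach comparable stress
        ospec = OptimizerSpec(name=optimizer_name, max_sweeps=3000)
    else:
        ospec = OptimizerSpec(name=optimizer_name)
    X0 = initialize(delta, p, seed)
    rng = np.random.default_rng((seed, 1))
    t0 = time.perf_counter()
    if optimizer_name == "majorization":
        emb = run_majorization(delta, sspec, X0, ospec)
    elif optimizer_name == "gauss_seidel_newton":
        emb = run_gauss_seidel_newton(delta, sspec, X0, ospec)
    elif optimizer_name == "sgd":
        emb = run_sgd(delta, sspec, X0, ospec, rng=rng)
    elif optimizer_name == "mcmc":
        emb = run_mcmc(delta, sspec, X0, ospec, rng=rng)
    else:
        emb = run_linear_iteration(delta, sspec, X0, ospec)
    emb.runtime_seconds = time.perf_counter() - t0
    emb.seed = seed
    return emb


def run_batch(delta, stress_name, optimizer_name, p=2, n_restarts=10,
              base_seed=0, stress_spec=None, opt_spec=None):
    """n_restarts independent seeded runs of one admissible pairing.

    Restart seeds are base_seed..base_seed + n_restarts - 1; the batch
    exposes the mean and standard error of the final stresses and the
    best run.
    """
    _check_pair(stress_name, optimizer_name)
    seeds = [base_seed + i for i in range(n_restarts)]
    runs = [embed(delta, stress_name, optimizer_name, p=p, seed=s,
                  stress_spec=stress_spec, opt_spec=opt_spec) for s in seeds]
    return RunBatch(runs=runs, n_restarts=n_restarts, seeds=seeds)
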