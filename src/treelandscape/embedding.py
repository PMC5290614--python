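"""Scikit-learn-style estimator wrapping the multi-restart NLDR machinery.

`NLDREmbedding` plays the role `sklearn.manifold.MDS` plays for metric
MDS: it consumes a precomputed dissimilarity matrix, runs a configurable
stress/optimizer pairing from several random starts, and exposes the
best embedding.  It composes with sklearn pipelines and model selection
through the standard get_params/set_params surface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_array, check_random_state

from .optimize import OptimizerSpec, run_batch
from .stress import StressSpec

__all__ = ["NLDREmbedding"]


class NLDREmbedding(BaseEstimator):
    """Nonlinear dimensionality reduction of a precomputed distance matrix.

    Parameters
    ----------
    n_components : int, default 3
        Target dimension of the landscape (2 or 3 for visualization).
    stress : {'normalized', 'kruskal1', 'nlm', 'cca'}, default 'cca'
        Cost function measuring the discrepancy between input and
        embedded distances.
    optimizer : {'majorization', 'gauss_seidel_newton', 'sgd', 'mcmc',
        'linear_iteration'}, default 'sgd'
        Must form an admissible pairing with ``stress`` (14 of the 16
        combinations are admissible).
    n_restarts : int, default 10
        Independent random starts; the best final stress wins.
    max_sweeps, tol : optimizer budget and convergence tolerance.
    cca_lambda0, cca_lambda_end : CCA neighborhood radius schedule
        (defaults: data diameter down to 5% of it).
    random_state : int or RandomState, optional
        Seeds the restart ensemble.

    Attributes
    ----------
    embedding_ : ndarray of shape (N, n_components)
        Coordinates of the best restart.
    stress_ : float
        Its final stress value.
    batch_ : RunBatch
        All restarts with seeds, stresses and runtimes.
    """

    def __init__(self, n_components=3, stress="cca", optimizer="sgd",
                 n_restarts=10, max_sweeps=1000, tol=1e-6,
                 cca_lambda0=None, cca_lambda_end=None, random_state=None):
        self.n_components = n_components
        self.stress = stress
        self.optimizer = optimizer
        self.n_restarts = n_restarts
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.cca_lambda0 = cca_lambda0
        self.cca_lambda_end = cca_lambda_end
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a precomputed symmetric dissimilarity matrix X (N x N)."""
        delta = getattr(X, "delta", X)
        delta = check_array(delta, dtype=float)
        if delta.shape[0] != delta.shape[1] or not np.allclose(delta, delta.T):
            raise ValueError("X must be a square symmetric dissimilarity matrix")
        rs = check_random_state(self.random_state)
        base_seed = int(rs.randint(0, 2**31 - self.n_restarts))
        sspec = StressSpec(name=self.stress, cca_lambda0=self.cca_lambda0,
                           cca_lambda_end=self.cca_lambda_end)
        ospec = OptimizerSpec(name=self.optimizer, max_sweeps=self.max_sweeps,
                              tol=self.tol)
        self.batch_ = run_batch(delta, self.stress, self.optimizer,
                                p=self.n_components, n_restarts=self.n_restarts,
                                base_seed=base_seed, stress_spec=sspec,
                                opt_spec=ospec)
        best = self.batch_.best
        self.embedding_ = best.X
        self.stress_ = best.final_stress
        self.n_iter_ = best.n_sweeps
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
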