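"""Numba inner loops for the stochastic per-pair / per-pivot optimizers."""

import numba as nb
import numpy as np


@nb.njit(cache=False)
def sgd_pair_sweep(X, I, J, delta, w, order, alpha):
    """One SGD sweep: visit pairs in ``order``, step both endpoints.

    Each visited pair (i, j) descends its own weighted squared-error term
    w * (delta - d)^2: endpoints move along +/-(x_i - x_j) by
    alpha * w * (delta - d) / d.  X is updated in place.
    """
    p = X.shape[1]
    for k in range(order.shape[0]):
        idx = order[k]
        i = I[idx]
        j = J[idx]
        d = 0.0
        for a in range(p):
            d += (X[i, a] - X[j, a]) ** 2
        d = np.sqrt(d)
        if d < 1e-12:
            continue
        coef = alpha * w[idx] * (delta[idx] - d) / d
        # trust region: never move an endpoint by more than half the
        # current separation (the Sammon 1/delta weights are unbounded)
        if coef > 0.5:
            coef = 0.5
        elif coef < -0.5:
            coef = -0.5
        for a in range(p):
            move = coef * (X[i, a] - X[j, a])
            X[i, a] += move
            X[j, a] -= move


@nb.njit(cache=False)
def cca_pivot_sweep(X, delta, order, alpha, lam):
    """One CCA sweep (Demartines-Herault): each pivot i moves every other
    point j whose *embedded* distance to the pivot is within lambda.

    The step-weight dependence on the output distance is what allows
    tearing: once a pair has been pushed beyond lambda it is left alone.
    """
    n, p = X.shape
    for k in range(n):
        i = order[k]
        for j in range(n):
            if j == i:
                continue
            d = 0.0
            for a in range(p):
                d += (X[j, a] - X[i, a]) ** 2
            d = np.sqrt(d)
            if d < 1e-12 or d > lam:
                continue
            coef = alpha * (delta[i, j] - d) / d
            if coef > 0.5:
                coef = 0.5
            elif coef < -0.5:
                coef = -0.5
            for a in range(p):
                X[j, a] += coef * (X[j, a] - X[i, a])
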