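"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different route than the
package (explicit completion of the square, exhaustive enumeration, a
hand-rolled Newton solver) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def nig_posterior_oracle(X, y, g, beta0):
    """Normal-inverse-gamma update by explicit completion of the square.

    Model: y = X beta + eps, eps ~ N(0, sigma^2 I);
    beta | sigma^2 ~ N(beta0, sigma^2 g (X'X)^-1) (scalar Zellner g);
    p(sigma^2) ~ 1/sigma^2.  Returns (mean, cov_factor, shape, scale) where
    the posterior of beta is N(mean, sigma^2 cov_factor) and sigma^2 is
    IG(shape, scale).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    beta0 = np.asarray(beta0, float)
    n = len(y)
    xtx = X.T @ X
    v_inv = np.linalg.inv(g * np.linalg.inv(xtx))
    precision = xtx + v_inv
    mean = np.linalg.solve(precision, X.T @ y + v_inv @ beta0)
    cov_factor = np.linalg.inv(precision)
    scale = 0.5 * (y @ y + beta0 @ v_inv @ beta0 - mean @ precision @ mean)
    return mean, cov_factor, n / 2.0, scale


def exact_density_pvalue(A, size, observed):
    """Exact permutation p for module density by exhausting all subsets."""
    A = np.asarray(A, float)
    n = A.shape[0]
    hits = total = 0
    for combo in itertools.combinations(range(n), size):
        idx = np.asarray(combo)
        sub = A[np.ix_(idx, idx)]
        dens = (sub.sum() - np.trace(sub)) / (size * (size - 1))
        total += 1
        if dens >= observed:
            hits += 1
    return hits / total


def cox_newton_oracle(x, time, event, n_iter=50):
    """Cox partial likelihood for one covariate, Newton-Raphson, no ties.

    Breslow/Efron coincide when all event times are distinct, so this tiny
    solver is a valid cross-check for that case.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    beta = 0.0
    for _ in range(n_iter):
        score = hess = 0.0
        for i in range(len(time)):
            if event[i] != 1:
                continue
            risk = slice(i, len(time))  # sorted: risk set = later-or-equal times
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            score += x[i] - s1 / s0
            hess += s2 / s0 - (s1 / s0) ** 2
        if hess <= 0:
            break
        step = score / hess
        beta += step
        if abs(step) < 1e-12:
            break
    return beta
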