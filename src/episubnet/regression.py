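"""Bayesian regression of response eigengenes on predictor eigengenes.

The dependence of a gene-expression response module on DNA-methylation
predictor modules is modelled as ordinary linear regression of eigengenes,

    y = X beta + eps,   eps ~ N(0, sigma^2 I),

with a Zellner g-prior beta | sigma^2 ~ N(beta0, g sigma^2 (X^T X)^-1) whose
weight is informed by the interaction network: g_ij = mu * r_ij with
relatedness r_ij = 2 E_ij / N_ij (cross-edge count over total gene count of
the two modules).  The g is extended to a vector, one entry per predictor,
giving per-coordinate shrinkage

    beta~_j = (g_j / (1 + g_j)) beta_ols_j          (beta0 = 0)

and an inverse-gamma posterior for sigma^2 with shape n/2 and scale

    b = SSR_ols/2 + (beta0 - beta_ols)^T G X^T X G (beta0 - beta_ols) / 2,

G = diag(sqrt(1/(1+g))).  Subsets of predictors are scored by the expected
BIC, E[BIC] = n E[ln sigma^2] + k ln n with E[ln sigma^2] = ln b - psi(n/2),
and the minimiser is the selected epigenetic subnetwork.  mu is tuned by
Fisher's combined probability over per-subnetwork permutation tests; mu = 0
denotes the no-prior OLS/BIC baseline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma

from .diffnet import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GPriorSpec",
    "RegressionFit",
    "SubnetworkFit",
    "biological_relatedness",
    "relatedness_matrix",
    "posterior_beta",
    "posterior_sigma2",
    "expected_bic",
    "best_subset",
    "no_prior_baseline",
    "coefficient_significance",
    "subnetwork_correlation_test",
    "confidence_score",
    "tune_mu",
]

_COND_LIMIT = 1e10


@dataclass
class GPriorSpec:
    """Network-informed g-prior: g_ij = mu * r_ij, prior mean beta0 = 0.

    ``r`` is a predictor x response relatedness matrix (rows indexed by
    predictor module ids, columns by response module ids).
    """

    r: pd.DataFrame
    mu: float

    def __post_init__(self) -> None:
        if (self.r.to_numpy() < 0).any():
            raise ValueError("relatedness must be nonnegative")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")

    def g_for(self, response, predictors) -> np.ndarray:
        """Per-predictor g vector for one response module."""
        return self.mu * self.r.loc[list(predictors), response].to_numpy(dtype=float)


@dataclass
class RegressionFit:
    response: object
    predictors: tuple
    beta_tilde: np.ndarray
    ols_beta: np.ndarray
    g: np.ndarray
    sigma2_shape: float
    sigma2_scale: float
    expected_bic: float
    coef_p: np.ndarray | None = None
    cov_scale: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma2_posterior_mean(self) -> float:
        if self.sigma2_shape <= 1:
            raise ValueError("posterior mean of sigma^2 undefined for shape <= 1")
        return self.sigma2_scale / (self.sigma2_shape - 1)


@dataclass
class SubnetworkFit:
    """A response module with its E[BIC]-selected predictor modules."""

    response: object
    predictors: tuple
    fit: RegressionFit
    correlation_p: float | None = None
    confidence: dict | None = None

    @property
    def any_significant(self) -> bool:
        if self.fit.coef_p is None:
            raise ValueError("coefficient p-values not computed")
        return bool(np.any(self.fit.coef_p < 0.05))


def biological_relatedness(pred_genes, resp_genes, ppi: InteractionNetwork) -> float:
    """r = 2 E / N: twice the cross-edge count over the total gene count."""
    pred, resp = set(pred_genes), set(resp_genes)
    if not pred or not resp:
        raise ValueError("empty gene set")
    e = ppi.cross_edge_count(pred, resp)
    return 2.0 * e / (len(pred) + len(resp))


def relatedness_matrix(
    predictor_modules: dict, response_modules: dict, ppi: InteractionNetwork
) -> pd.DataFrame:
    """Predictor x response relatedness r_ij = 2 E_ij / N_ij for all pairs."""
    data = {
        rid: [
            biological_relatedness(pgenes, rgenes, ppi)
            for pgenes in predictor_modules.values()
        ]
        for rid, rgenes in response_modules.items()
    }
    return pd.DataFrame(data, index=list(predictor_modules.keys()))


def _design(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n != len(y):
        raise ValueError("X and y sample counts differ")
    if n <= k:
        raise ValueError(f"need more samples ({n}) than predictors ({k})")
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_LIMIT:
        raise ValueError("rank-deficient design: predictors are collinear")
    return X, y, xtx


def posterior_beta(X, y, g, beta0=None):
    """Posterior-mean coefficients and the sigma^2-free covariance factor.

    Returns ``(beta_tilde, cov_scale)`` where the posterior covariance of
    beta is ``sigma^2 * cov_scale`` with
    cov_scale = S (X^T X)^-1 S, S = diag(sqrt(g/(1+g))).  Per-coordinate
    shrinkage: beta_tilde_j = (g_j beta0_j / (1+g_j) ... ) reduces to
    (g_j/(1+g_j)) beta_ols_j for beta0 = 0; g -> inf gives OLS, g = 0
    returns beta0.
    """
    X, y, xtx = _design(X, y)
    k = X.shape[1]
    g = np.broadcast_to(np.asarray(g, dtype=float), (k,)).copy()
    if (g < 0).any():
        raise ValueError("g must be nonnegative")
    beta0 = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float)
    ols = np.linalg.solve(xtx, X.T @ y)
    w = g / (1.0 + g)
    beta_tilde = w * ols + (1.0 - w) * beta0
    s = np.sqrt(w)
    cov_scale = (s[:, None] * np.linalg.inv(xtx)) * s[None, :]
    return beta_tilde, cov_scale


def posterior_sigma2(X, y, g, beta0=None):
    """Inverse-gamma posterior (shape, scale) of the error variance.

    shape = n/2; scale = SSR(beta_ols)/2 + quadratic shrinkage penalty
    (beta0 - beta_ols)^T G X^T X G (beta0 - beta_ols)/2 with
    G = diag(sqrt(1/(1+g))).
    """
    X, y, xtx = _design(X, y)
    k = X.shape[1]
    g = np.broadcast_to(np.asarray(g, dtype=float), (k,)).copy()
    beta0 = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float)
    ols = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ ols
    ssr = float(resid @ resid)
    diff = (beta0 - ols) / np.sqrt(1.0 + g)
    quad = float(diff @ xtx @ diff)
    a = X.shape[0] / 2.0
    b = ssr / 2.0 + quad / 2.0
    if b <= 0:
        raise ValueError("degenerate inputs: posterior scale b <= 0")
    return a, b


def expected_bic(X, y, g, beta0=None, n: int | None = None) -> float:
    """E[BIC] = n E[ln sigma^2] + k ln n, E[ln sigma^2] = ln b - psi(n/2)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n is None:
        n = X.shape[0]
    a, b = posterior_sigma2(X, y, g, beta0)
    e_log_sigma2 = np.log(b) - digamma(a)
    return float(n * e_log_sigma2 + X.shape[1] * np.log(n))


def _subsets(predictors, max_size: int, exhaustive_limit: int = 15):
    """Nonempty predictor subsets, smaller sizes first then lexicographic."""
    preds = list(predictors)
    cap = len(preds) if len(preds) <= exhaustive_limit else min(max_size, len(preds))
    for size in range(1, cap + 1):
        yield from itertools.combinations(preds, size)


def coefficient_significance(fit: RegressionFit) -> np.ndarray:
    """Two-sided z-test of beta = 0 under the posterior.

    Uses the posterior mean of beta and the marginal posterior scale with
    sigma^2 plugged in at its posterior mean b/(a-1).  A fully shrunk
    coefficient (beta~ = 0 with zero posterior scale) gets p = 1.
    """
    if fit.cov_scale is None:
        raise ValueError("fit lacks the posterior covariance factor")
    sigma2 = fit.sigma2_posterior_mean
    var = sigma2 * np.diag(fit.cov_scale)
    p = np.ones_like(fit.beta_tilde)
    ok = var > 0
    z = np.zeros_like(fit.beta_tilde)
    z[ok] = fit.beta_tilde[ok] / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    p[~ok & (fit.beta_tilde != 0)] = 0.0  # zero variance, nonzero mean
    return p


def _fit_gprior(X, y, g, predictors, response) -> RegressionFit:
    beta_tilde, cov_scale = posterior_beta(X, y, g)
    a, b = posterior_sigma2(X, y, g)
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ols = np.linalg.solve(Xa.T @ Xa, Xa.T @ np.asarray(y, dtype=float))
    ebic = expected_bic(X, y, g)
    fit = RegressionFit(
        response=response,
        predictors=tuple(predictors),
        beta_tilde=beta_tilde,
        ols_beta=ols,
        g=np.broadcast_to(np.asarray(g, dtype=float), (Xa.shape[1],)).copy(),
        sigma2_shape=a,
        sigma2_scale=b,
        expected_bic=ebic,
        cov_scale=cov_scale,
    )
    fit.coef_p = coefficient_significance(fit)
    return fit


def best_subset(
    X_all: pd.DataFrame,
    y,
    gspec: GPriorSpec,
    response=None,
    max_size: int = 5,
) -> SubnetworkFit:
    """Exhaustive E[BIC] search over predictor subsets for one response.

    ``X_all`` holds one standardised predictor-eigengene column per
    predictor module.  All nonempty subsets are scored (all sizes when
    there are <= 15 predictors, else up to ``max_size``); ties prefer the
    smaller, then lexicographically earlier, subset.
    """
    if X_all.shape[1] < 1:
        raise ValueError("need at least one predictor")
    y = np.asarray(y, dtype=float).ravel()
    best_fit = None
    for subset in _subsets(X_all.columns, max_size):
        g = gspec.g_for(response, subset)
        fit = _fit_gprior(X_all.loc[:, list(subset)].to_numpy(), y, g, subset, response)
        if best_fit is None or fit.expected_bic < best_fit.expected_bic - 1e-12:
            best_fit = fit
    assert best_fit is not None
    return SubnetworkFit(response=response, predictors=best_fit.predictors, fit=best_fit)


def no_prior_baseline(X_all: pd.DataFrame, y, response=None, max_size: int = 5) -> SubnetworkFit:
    """OLS subset selection by classical BIC (the mu = 0 baseline).

    BIC = n ln(SSR/n) + k ln n with the Gaussian likelihood profiled over
    sigma^2; coefficient significance by the usual OLS t-test.
    """
    if X_all.shape[1] < 1:
        raise ValueError("need at least one predictor")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    best = None
    for subset in _subsets(X_all.columns, max_size):
        X, yv, xtx = _design(X_all.loc[:, list(subset)].to_numpy(), y)
        k = X.shape[1]
        ols = np.linalg.solve(xtx, X.T @ yv)
        resid = yv - X @ ols
        ssr = float(resid @ resid)
        bic = n * np.log(max(ssr, np.finfo(float).tiny) / n) + k * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, subset, ols, ssr, xtx)
    bic, subset, ols, ssr, xtx = best
    k = len(subset)
    sigma2_hat = ssr / (n - k)
    se = np.sqrt(sigma2_hat * np.diag(np.linalg.inv(xtx)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, ols / se, 0.0)
    coef_p = 2.0 * stats.t.sf(np.abs(tstat), df=n - k)
    fit = RegressionFit(
        response=response,
        predictors=tuple(subset),
        beta_tilde=ols,
        ols_beta=ols,
        g=np.full(k, np.inf),
        sigma2_shape=n / 2.0,
        sigma2_scale=ssr / 2.0,
        expected_bic=bic,
        coef_p=coef_p,
        cov_scale=np.linalg.inv(xtx),
    )
    return SubnetworkFit(response=response, predictors=fit.predictors, fit=fit)


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return 1.0 - float(resid @ resid) / tss


def subnetwork_correlation_test(X_sub, y, B: int = 1000, seed: int = 0) -> float:
    """Permutation test of the response-on-predictors R^2.

    The sample order of the response eigengene is permuted B times; the
    p-value is (1 + #{null R^2 >= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(X_sub, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] < 1:
        raise ValueError("need at least one selected predictor")
    y = np.asarray(y, dtype=float).ravel()
    Xd = np.column_stack([np.ones(len(y)), X])  # intercept for the R^2 null
    observed = _r_squared(Xd, y)
    rng = np.random.default_rng(seed)
    hits = 0
    # Projection is fixed: precompute the hat decomposition once.
    q, _ = np.linalg.qr(Xd)
    for _ in range(B):
        yp = rng.permutation(y)
        ypc = yp - yp.mean()
        tss = float(ypc @ ypc)
        if tss <= 0:
            continue
        fitted = q @ (q.T @ yp)
        resid = yp - fitted
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (B + 1)


def confidence_score(sub: SubnetworkFit, X_all: pd.DataFrame, y) -> dict:
    """Per-predictor incremental R^2 (drop-one variance contribution).

    The score of predictor x in the selected subset is R^2(full subset) -
    R^2(subset without x), clipped at 0; for a single-predictor subnetwork
    it equals the fit's R^2.  A stand-in for an unspecified published
    score, labelled as incremental R^2 in all outputs.
    """
    y = np.asarray(y, dtype=float).ravel()
    subset = list(sub.predictors)
    Xfull = np.column_stack([np.ones(len(y)), X_all.loc[:, subset].to_numpy()])
    r2_full = _r_squared(Xfull, y)
    scores = {}
    for pred in subset:
        rest = [p for p in subset if p != pred]
        if rest:
            Xr = np.column_stack([np.ones(len(y)), X_all.loc[:, rest].to_numpy()])
            r2_rest = _r_squared(Xr, y)
        else:
            r2_rest = 0.0
        scores[pred] = max(0.0, r2_full - r2_rest)
    return scores


def fit_all_responses(
    X_all: pd.DataFrame,
    responses: pd.DataFrame,
    gspec: GPriorSpec | None,
    max_size: int = 5,
) -> dict:
    """Subset selection for every response eigengene (g-prior or baseline)."""
    fits = {}
    for rid in responses.index:
        y = responses.loc[rid].to_numpy(dtype=float)
        if gspec is None or gspec.mu == 0:
            fits[rid] = no_prior_baseline(X_all, y, response=rid, max_size=max_size)
        else:
            fits[rid] = best_subset(X_all, y, gspec, response=rid, max_size=max_size)
    return fits


def tune_mu(
    X_all: pd.DataFrame,
    responses: pd.DataFrame,
    r: pd.DataFrame,
    mu_grid,
    B: int = 1000,
    seed: int = 0,
    max_size: int = 5,
):
    """Pick the prior weight mu by Fisher's combined probability.

    For each mu on the grid, subsets are selected for every response
    (mu = 0 -> no-prior baseline), each subnetwork's R^2 permutation
    p-value is computed, and the p-values are combined as
    chi^2 = -2 sum ln p with 2 x #subnetworks degrees of freedom.  Returns
    (mu*, table of per-mu meta statistics); ties prefer the smallest mu.
    Zero p-values are replaced by 1/(B+1) before the log (logged) -- the
    permutation p already has that floor by construction.
    """
    mu_grid = sorted(set(float(m) for m in mu_grid))
    if not mu_grid:
        raise ValueError("empty mu grid")
    ss = np.random.SeedSequence(seed)
    # One permutation stream per response, shared across the mu grid, so the
    # comparison of mu values is paired (identical fits -> identical p).
    perm_seeds = {
        rid: int(s.generate_state(1)[0] % (2**31))
        for rid, s in zip(responses.index, ss.spawn(len(responses.index)))
    }
    rows = []
    best = None
    for mu in mu_grid:
        gspec = GPriorSpec(r=r, mu=mu) if mu > 0 else None
        fits = fit_all_responses(X_all, responses, gspec, max_size=max_size)
        pvals = []
        for rid, sub in fits.items():
            y = responses.loc[rid].to_numpy(dtype=float)
            p = subnetwork_correlation_test(
                X_all.loc[:, list(sub.predictors)].to_numpy(), y,
                B=B, seed=perm_seeds[rid],
            )
            if p <= 0:
                logger.warning("zero permutation p replaced by 1/(B+1)")
                p = 1.0 / (B + 1)
            sub.correlation_p = p
            pvals.append(p)
        chi2 = -2.0 * float(np.sum(np.log(pvals)))
        meta_p = float(stats.chi2.sf(chi2, df=2 * len(pvals)))
        rows.append((mu, chi2, meta_p, -np.log10(max(meta_p, 1e-300))))
        if best is None or meta_p < best[1] - 1e-300:
            best = (mu, meta_p, fits)
    table = pd.DataFrame(rows, columns=["mu", "chi2", "meta_p", "neg_log10_meta_p"]).set_index("mu")
    return best[0], table, best[2]
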