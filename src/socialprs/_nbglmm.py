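"""Negative-binomial GLMM with a single Gaussian random intercept.

Marginal likelihood by adaptive Gauss-Hermite quadrature: per group the
integrand is maximised by 1-D Newton steps (vectorised across groups), and
the quadrature grid is centred and scaled at that mode. Parameters are the
fixed-effect coefficients, log(alpha) for the NB2 dispersion
(var = mu + alpha mu^2) and log(sigma) for the random-intercept SD;
optimisation is bounded quasi-Newton on the transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize

_LOG_SIGMA_FLOOR = -10.0  # sigma ~ 4.5e-5: effectively the fixed-effects model


@dataclass
class NBGLMMResult:
    params: np.ndarray     # fixed effects
    bse: np.ndarray
    llf: float
    alpha: float           # NB2 dispersion
    sigma: float           # random-intercept SD
    converged: bool
    n_groups: int


def _nb_loglik_terms(y, eta, alpha):
    """Per-observation NB2 log pmf with mean exp(eta) and var mu + alpha mu^2."""
    from scipy.special import gammaln

    k = 1.0 / alpha
    mu = np.exp(eta)
    return (gammaln(y + k) - gammaln(k) - gammaln(y + 1)
            + y * (eta - np.log(mu + k)) + k * (np.log(k) - np.log(mu + k)))


def _group_loglik(y, eta0, alpha, sigma, group_idx, n_groups, nodes, weights,
                  newton_iter: int = 25):
    """log marginal likelihood per group by adaptive Gauss-Hermite."""
    k = 1.0 / alpha

    def h_parts(u_per_group):
        u = u_per_group[group_idx]
        mu = np.exp(eta0 + u)
        # d/du and d2/du2 of sum_i log NB(y_i | mu_i e^u) within group
        g_i = y - (y + k) * mu / (mu + k)
        hpp_i = -(y + k) * k * mu / (mu + k) ** 2
        g = np.bincount(group_idx, weights=g_i, minlength=n_groups)
        hpp = np.bincount(group_idx, weights=hpp_i, minlength=n_groups)
        return g - u_per_group / sigma ** 2, hpp - 1.0 / sigma ** 2

    # mode finding: damped Newton, vectorised across groups
    u_hat = np.zeros(n_groups)
    for _ in range(newton_iter):
        g, hpp = h_parts(u_hat)
        step = g / hpp
        step = np.clip(step, -2.0, 2.0)
        u_new = u_hat - step
        if np.max(np.abs(u_new - u_hat)) < 1e-10:
            u_hat = u_new
            break
        u_hat = u_new
    _, hpp = h_parts(u_hat)
    s = 1.0 / np.sqrt(np.maximum(-hpp, 1e-12))

    # AGQ: int e^{h(u)} du ~= sum_k w_k s e^{t_k^2/2} e^{h(u_hat + s t_k)}
    # (hermegauss nodes/weights are for weight e^{-t^2/2})
    acc = np.full(n_groups, -np.inf)
    log_phi_const = -0.5 * np.log(2 * np.pi) - np.log(sigma)
    vals = np.empty((len(nodes), n_groups))
    for j, (t, w) in enumerate(zip(nodes, weights)):
        u = u_hat + s * t
        eta = eta0 + u[group_idx]
        ll_i = _nb_loglik_terms(y, eta, alpha)
        ll_g = np.bincount(group_idx, weights=ll_i, minlength=n_groups)
        h = ll_g + log_phi_const - 0.5 * (u / sigma) ** 2
        vals[j] = np.log(w) + np.log(s) + 0.5 * t * t + h
    m = vals.max(axis=0)
    acc = m + np.log(np.exp(vals - m).sum(axis=0))
    return acc


def nbglmm_loglik(theta, y, X, group_idx, n_groups, nodes, weights):
    p = X.shape[1]
    beta, log_alpha, log_sigma = theta[:p], theta[p], theta[p + 1]
    alpha = np.exp(log_alpha)
    eta0 = X @ beta
    if log_sigma <= _LOG_SIGMA_FLOOR + 1e-9:
        return float(_nb_loglik_terms(y, eta0, alpha).sum())
    sigma = np.exp(log_sigma)
    return float(_group_loglik(y, eta0, alpha, sigma, group_idx,
                               n_groups, nodes, weights).sum())


def fit_nbglmm(y, X, groups, n_quad: int = 8, start=None,
               maxiter: int = 200) -> NBGLMMResult:
    """Fit the NB random-intercept model by maximum marginal likelihood."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = _factorize(groups)
    n_groups = int(codes.max()) + 1
    nodes, weights = hermegauss(n_quad)
    p = X.shape[1]

    if start is None:
        import statsmodels.api as sm

        fe = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        start = np.concatenate([fe.params[:p],
                                [np.log(max(fe.params[p], 1e-3))], [-1.5]])
    bounds = [(None, None)] * p + [(-12, 6), (_LOG_SIGMA_FLOOR, 3)]

    def nll(theta):
        return -nbglmm_loglik(theta, y, X, codes, n_groups, nodes, weights)

    res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-11})
    theta = res.x
    hess = _numeric_hessian(nll, theta)
    # SEs for fixed effects from the full-parameter observed information
    try:
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return NBGLMMResult(params=theta[:p], bse=bse, llf=-res.fun,
                        alpha=float(np.exp(theta[p])),
                        sigma=float(np.exp(theta[p + 1])),
                        converged=bool(res.success), n_groups=n_groups)


def _factorize(groups):
    import pandas as pd

    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(np.int64), uniques


def _numeric_hessian(f, x, eps: float = 1e-4):
    n = len(x)
    H = np.empty((n, n))
    fx = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fij = f(x + ei + ej)
            fi = f(x + ei)
            fj = f(x + ej)
            H[i, j] = H[j, i] = (fij - fi - fj + fx) / (steps[i] * steps[j])
    return H
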