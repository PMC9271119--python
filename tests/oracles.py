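"""Independent brute-force oracles for the mixed-model engine.

These deliberately use dense N x N algebra and generic optimizers, sharing no
code with the package's n_g-reduced REML path.
"""

import numpy as np
from scipy.optimize import minimize


def dense_reml_loglik(y, X, V):
    """Residual log-likelihood of y ~ N(X b, V), constants included."""
    N, p = X.shape
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XVX, X.T @ Vi)
    _, ldV = np.linalg.slogdet(V)
    _, ldC = np.linalg.slogdet(XVX)
    return -0.5 * (ldV + ldC + float(y @ P @ y) + (N - p) * np.log(2 * np.pi))


def dense_reml_fit(y, X, covs, start=None):
    """Maximize the dense residual likelihood over one variance per
    covariance matrix in ``covs`` (the last entry should be the identity for
    the residual).  Returns (variances, loglik)."""
    start = np.log(np.full(len(covs), 0.5)) if start is None else np.log(start)

    def negll(theta):
        V = sum(np.exp(t) * C for t, C in zip(theta, covs))
        return -dense_reml_loglik(y, X, V)

    res = minimize(negll, start, method="Nelder-Mead",
                   options=dict(xatol=1e-11, fatol=1e-13,
                                maxiter=40000, maxfev=40000))
    return np.exp(res.x), -res.fun


def mme_blups(y, X, Z_list, sigma2_list, sigma2_e):
    """Solve Henderson's mixed-model equations for fixed effects and the
    BLUPs of each random block, plus prediction error variances.

    Z_list[k] is the N x q_k design of random block k with prior
    sigma2_list[k] * I.  Returns (beta, [u_k], [pev_k]) with pev_k the
    prediction error variance matrix of block k from the inverse
    coefficient matrix.
    """
    Z = np.hstack(Z_list)
    q = Z.shape[1]
    Ginv = np.zeros((q, q))
    off = 0
    for Zk, s2 in zip(Z_list, sigma2_list):
        k = Zk.shape[1]
        Ginv[off:off + k, off:off + k] = np.eye(k) / s2
        off += k
    p = X.shape[1]
    C = np.block([
        [X.T @ X, X.T @ Z],
        [Z.T @ X, Z.T @ Z + sigma2_e * Ginv],
    ])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    beta = sol[:p]
    us, pevs = [], []
    off = p
    for Zk in Z_list:
        k = Zk.shape[1]
        us.append(sol[off:off + k])
        pevs.append(sigma2_e * Cinv[off:off + k, off:off + k])
        off += k
    return beta, us, pevs


def balanced_oneway_reml(y_groups):
    """Closed-form REML (ANOVA estimators, truncated at 0) for a balanced
    one-way random-effects layout: y_groups of shape (a, n)."""
    a, n = y_groups.shape
    group_means = y_groups.mean(axis=1)
    grand = y_groups.mean()
    msb = n * ((group_means - grand) ** 2).sum() / (a - 1)
    msw = ((y_groups - group_means[:, None]) ** 2).sum() / (a * (n - 1))
    s2_between = max((msb - msw) / n, 0.0)
    if s2_between > 0:
        return s2_between, msw
    # boundary: refit residual as pooled variance
    pooled = ((y_groups - grand) ** 2).sum() / (a * n - 1)
    return 0.0, pooled
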