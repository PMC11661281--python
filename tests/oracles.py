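"""Independent reference implementations used only to cross-check fits.

These deliberately avoid the code paths they validate: the linear mixed
model oracle numerically maximizes the REML marginal likelihood built from
dense covariance matrices, and the weighted logistic oracle maximizes the
exact weighted log-likelihood with a generic simplex optimizer.
"""

import numpy as np
from scipy import optimize


def reml_random_intercept(y, X, groups):
    """REML fit of y = X beta + u_group + e by direct optimization of the
    restricted marginal likelihood; returns (beta, se_beta, sd_u, sd_e)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    n, p = X.shape
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0

    def neg_reml(theta):
        su2, se2 = np.exp(2 * theta)
        V = su2 * Z @ Z.T + se2 * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        logdetV = 2 * np.sum(np.log(np.diag(L)))
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        return 0.5 * (logdetV + logdetXtViX + r @ np.linalg.solve(V, r))

    res = optimize.minimize(neg_reml, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    su2, se2 = np.exp(2 * res.x)
    V = su2 * Z @ Z.T + se2 * np.eye(n)
    Vi_X = np.linalg.solve(V, X)
    cov_beta = np.linalg.inv(X.T @ Vi_X)
    beta = cov_beta @ (X.T @ np.linalg.solve(V, y))
    return beta, np.sqrt(np.diag(cov_beta)), np.sqrt(su2), np.sqrt(se2)


def weighted_logistic_mle(y, X, weights, x0=None):
    """Exact maximizer of the weighted Bernoulli log-likelihood by
    Nelder-Mead (small problems only)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    w = np.asarray(weights, float)

    def negll(beta):
        eta = X @ beta
        return -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))

    x0 = np.zeros(X.shape[1]) if x0 is None else x0
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x
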