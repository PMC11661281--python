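"""Weighted logistic regression with Gaussian random intercepts.

Fits, by Laplace approximation, the marginal likelihood of a logistic
mixed model with per-observation weights

    y_i ~ Bernoulli(logit^{-1}(x_i' beta + u_{g(i)})),  u_g ~ N(0, sigma^2),

where each observation's log-likelihood contribution is multiplied by a
non-negative weight.  Random intercepts make the conditional-mode Hessian
block-diagonal in u, so the inner Newton step costs O(n p^2 + G) and the
profile over log(sigma) is a cheap 1-D search.

Wald standard errors for the fixed effects come from the Schur complement
of the joint (beta, u) Hessian at the optimum, conditional on the
estimated variance — the conventional GLMM Wald covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class LogisticMixedFit:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma: float
    random_effects: np.ndarray
    loglik: float
    converged: bool


def _penalized_newton(y, X, w, codes, G, sigma2, beta, u, max_iter=50, tol=1e-8):
    """Maximize the u-penalized weighted log-likelihood jointly over
    (beta, u) by block-elimination Newton; returns mode and curvature parts."""
    n, p = X.shape
    for _ in range(max_iter):
        eta = X @ beta + u[codes]
        mu = 1.0 / (1.0 + np.exp(-eta))
        wv = w * mu * (1.0 - mu)
        wv = np.maximum(wv, 1e-10)
        resid = w * (y - mu)
        g_beta = X.T @ resid
        g_u = np.bincount(codes, weights=resid, minlength=G) - u / sigma2
        A = X.T @ (X * wv[:, None])
        Bm = np.zeros((p, G))
        for j in range(p):
            Bm[j] = np.bincount(codes, weights=X[:, j] * wv, minlength=G)
        d = np.bincount(codes, weights=wv, minlength=G) + 1.0 / sigma2
        # Schur complement solve of [[A, B], [B', diag(d)]]
        Bd = Bm / d
        S = A - Bd @ Bm.T
        try:
            step_beta = np.linalg.solve(S, g_beta - Bd @ g_u)
        except np.linalg.LinAlgError:
            step_beta = np.linalg.lstsq(S, g_beta - Bd @ g_u, rcond=None)[0]
        step_u = (g_u - Bm.T @ step_beta) / d
        # dampen huge steps for stability
        scale = max(1.0, np.max(np.abs(step_beta)) / 5.0)
        beta = beta + step_beta / scale
        u = u + step_u / scale
        if max(np.max(np.abs(step_beta)), np.max(np.abs(step_u))) < tol:
            break
    eta = X @ beta + u[codes]
    mu = 1.0 / (1.0 + np.exp(-eta))
    wv = np.maximum(w * mu * (1.0 - mu), 1e-10)
    d = np.bincount(codes, weights=wv, minlength=G) + 1.0 / sigma2
    ll_data = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
    return beta, u, ll_data, d, wv


def _laplace_loglik(y, X, w, codes, G, sigma2, beta0, u0):
    beta, u, ll_data, d, _ = _penalized_newton(y, X, w, codes, G, sigma2, beta0, u0)
    ll = ll_data - np.sum(u**2) / (2 * sigma2) - 0.5 * G * np.log(sigma2) - 0.5 * np.sum(
        np.log(d)
    )
    return ll, beta, u


def fit_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    weights: np.ndarray | None = None,
    log_sigma_bounds: tuple[float, float] = (-4.0, 2.5),
) -> LogisticMixedFit:
    """Fit the weighted random-intercept logistic model.

    Parameters
    ----------
    y, X:
        binary response and fixed-effects design (with intercept column).
    groups:
        per-observation group labels (any hashable); one random intercept
        per distinct label.
    weights:
        per-observation likelihood weights (default all 1).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    G = int(codes.max()) + 1
    p = X.shape[1]

    state = {"beta": np.zeros(p), "u": np.zeros(G)}

    def neg_profile(log_sigma: float) -> float:
        sigma2 = float(np.exp(2 * log_sigma))
        ll, beta, u = _laplace_loglik(y, X, w, codes, G, sigma2, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        return -ll

    res = minimize_scalar(
        neg_profile, bounds=log_sigma_bounds, method="bounded", options={"xatol": 1e-3}
    )
    sigma = float(np.exp(res.x))
    sigma2 = sigma**2
    beta, u, ll_data, d, wv = _penalized_newton(
        y, X, w, codes, G, sigma2, state["beta"], state["u"], max_iter=100
    )
    loglik = (
        ll_data
        - np.sum(u**2) / (2 * sigma2)
        - 0.5 * G * np.log(sigma2)
        - 0.5 * np.sum(np.log(d))
    )
    A = X.T @ (X * wv[:, None])
    Bm = np.zeros((p, G))
    for j in range(p):
        Bm[j] = np.bincount(codes, weights=X[:, j] * wv, minlength=G)
    S = A - (Bm / d) @ Bm.T
    try:
        cov = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(S)
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    converged = bool(res.success) and np.all(np.isfinite(beta)) and np.all(np.isfinite(bse))
    return LogisticMixedFit(
        params=beta,
        bse=bse,
        cov_params=cov,
        sigma=sigma,
        random_effects=u,
        loglik=float(loglik),
        converged=converged,
    )
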