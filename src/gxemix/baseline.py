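"""Plain logistic lasso, fit by IRLS with cyclic coordinate descent.

A deliberately simple, self-contained baseline: no groups, no random
effects, no interactions.  It provides (a) a reference comparator for
benchmarking the mixed-model path and (b) an independent oracle for the
degeneracy check: with the kinship set to the identity and the genetic
random-effect variance driven to zero, the mixed-model path must collapse
onto this solver's path.

The objective is the sum (not mean) negative log-likelihood plus
``lam * sum_j |beta_j|``; the intercept and any extra unpenalized
covariates are not penalized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic_lasso", "logistic_lasso_path"]


def _expit(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    X_unpen: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    coef_unpen0: np.ndarray | None = None,
    max_irls: int = 100,
    max_cd: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ``-sum_i log p(y_i | x_i) + lam * ||beta||_1``.

    Returns ``(coef_unpen, beta)``; ``X_unpen`` defaults to an intercept
    column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if X_unpen is None:
        X_unpen = np.ones((n, 1))
    c = np.zeros(X_unpen.shape[1]) if coef_unpen0 is None else coef_unpen0.copy()
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = X_unpen @ c + X @ beta
    for _ in range(max_irls):
        mu = np.clip(_expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        res = z - eta
        Lj = X.T**2 @ w  # per-coordinate curvature
        A = X_unpen.T @ (w[:, None] * X_unpen)
        for _cd in range(max_cd):
            change = 0.0
            d0 = np.linalg.solve(A, X_unpen.T @ (w * res))
            c += d0
            res -= X_unpen @ d0
            change = max(change, float(np.max(np.abs(d0))) if d0.size else 0.0)
            for j in range(p):
                u = beta[j] * Lj[j] + float(X[:, j] @ (w * res))
                new = np.sign(u) * max(abs(u) - lam, 0.0) / Lj[j]
                d = new - beta[j]
                if d != 0.0:
                    beta[j] = new
                    res -= X[:, j] * d
                    change = max(change, abs(d))
            if change < tol:
                break
        eta_new = X_unpen @ c + X @ beta
        if np.max(np.abs(eta_new - eta)) < 1e-9:
            eta = eta_new
            break
        eta = eta_new
    return c, beta


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    X_unpen: np.ndarray | None = None,
    **kwargs,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Warm-started lasso path over a decreasing lambda sequence."""
    out = []
    c, beta = None, None
    for lam in lambdas:
        c, beta = logistic_lasso(
            X, y, float(lam), X_unpen=X_unpen, beta0=beta, coef_unpen0=c,
            **kwargs,
        )
        out.append((c.copy(), beta.copy()))
    return out
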