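"""Variance-component estimation under the null model of no genetic effect.

The variance components ``(tau_g, tau_d)`` of the two-kinship random effect
``b ~ N(0, tau_g K + tau_d K_D)`` (and the dispersion ``phi`` for gaussian
responses) are estimated once, assuming all SNP main effects and GEI effects
are zero.  Estimation alternates

1. a penalized quasi-likelihood (PQL) inner loop: iterated weighted least
   squares for the covariate effects and the random-effect vector at fixed
   variance components, and
2. average-information REML (AI-REML) Newton updates of the variance
   components on the working linear mixed model with response
   ``z = eta + (y - mu) g'(mu)`` and covariance ``V = W^-1 + tau_g K +
   tau_d K_D``.

This two-step scheme avoids re-estimating the ``O(n^3)`` variance components
inside the regularization path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .families import FamilySpec, binomial

__all__ = ["NullFit", "working_weights", "pql_working_fit", "fit_null_pql_aireml"]


@dataclass
class NullFit:
    """Null-model estimates: covariate effects, exposure effect, variance
    components, dispersion and predicted random effects."""

    theta: np.ndarray
    alpha: float
    tau_g: float
    tau_d: float
    phi: float
    b: np.ndarray
    converged: bool
    n_iter: int
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eta: np.ndarray | None = None

    @property
    def tau(self) -> tuple[float, float]:
        return (self.tau_g, self.tau_d)


def working_weights(
    mu: np.ndarray,
    family: FamilySpec,
    a: np.ndarray | None = None,
    phi: float | None = None,
) -> np.ndarray:
    """GLM working weights ``w_i = a_i / (phi * nu(mu_i) * g'(mu_i)^2)``.

    For the canonical binomial family this reduces to
    ``a_i mu_i (1 - mu_i) / phi`` and for the gaussian identity family to
    ``a_i / phi``.
    """
    mu = np.asarray(mu, dtype=float)
    family.check_mu(mu)
    if family.name == "binomial" and (np.any(mu <= 0) or np.any(mu >= 1)):
        raise ValueError("mu on the boundary of (0, 1)")
    a = np.ones_like(mu) if a is None else np.asarray(a, dtype=float)
    phi = family.phi if phi is None else phi
    w = a / (phi * family.variance(mu) * family.dlink(mu) ** 2)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("non-positive or non-finite working weight")
    return w


def _irls_glm(y, X, family, a, max_iter=50, tol=1e-10):
    """Plain IRLS fit of a GLM (no random effects); returns (coef, eta, mu)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if family.name == "binomial":
        mu = (y + 0.5) / 2.0
    else:
        mu = np.full(n, y.mean())
        mu = 0.9 * mu + 0.1 * y
    eta = family.link(np.clip(mu, 1e-6, 1 - 1e-6) if family.name == "binomial" else mu)
    coef = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = family.inverse_link(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10) if family.name == "binomial" else mu
        w = working_weights(mu, family, a)
        z = eta + (y - mu) * family.dlink(mu)
        WX = w[:, None] * X
        coef_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta_new = X @ coef_new
        if np.max(np.abs(eta_new - eta)) < tol:
            coef, eta = coef_new, eta_new
            break
        coef, eta = coef_new, eta_new
    return coef, eta, family.inverse_link(eta)


def pql_working_fit(
    y: np.ndarray,
    X: np.ndarray,
    Sigma: np.ndarray | None,
    family: FamilySpec,
    a: np.ndarray | None = None,
    phi: float | None = None,
    coef0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Inner PQL loop at fixed random-effect covariance ``Sigma``.

    Maximizes the penalized quasi-likelihood
    ``sum_i ql_i(eta) - b' Sigma^-1 b / 2`` over the covariate effects and
    random-effect vector, by iterated GLS on the working model with a
    step-halving safeguard that keeps the objective non-decreasing.

    Returns ``(coef, b, eta, objective_history, converged)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    a = np.ones(n) if a is None else np.asarray(a, dtype=float)
    phi = family.phi if phi is None else phi
    no_ranef = Sigma is None or not np.any(Sigma)

    coef = np.zeros(X.shape[1]) if coef0 is None else np.array(coef0, dtype=float)
    b = np.zeros(n) if b0 is None else np.array(b0, dtype=float)
    q = np.zeros(n)  # q = Sigma^-1 b, tracked alongside b
    if b0 is not None and not no_ranef and np.any(b0):
        q = np.linalg.solve(Sigma, b)
    eta = X @ coef + b

    def pen_obj(eta_c, b_c, q_c):
        return -family.neg_quasi_loglik(y, eta_c, a) - 0.5 * float(b_c @ q_c)

    history = [pen_obj(eta, b, q)]
    converged = False
    for _ in range(max_iter):
        mu = family.inverse_link(eta)
        if family.name == "binomial":
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = working_weights(mu, family, a, phi)
        z = eta + (y - mu) * family.dlink(mu)
        if no_ranef:
            WX = w[:, None] * X
            coef_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            b_new, q_new = b, q
        else:
            V = Sigma + np.diag(1.0 / w)
            cho = cho_factor(V, lower=True)
            Viz = cho_solve(cho, z)
            ViX = cho_solve(cho, X)
            coef_new = np.linalg.solve(X.T @ ViX, X.T @ Viz)
            q_new = cho_solve(cho, z - X @ coef_new)  # = Sigma^-1 b_new
            b_new = Sigma @ q_new
        # step-halving: the GLS step is a Newton-type step on the working
        # model; damp it if the true penalized objective would decrease
        step = 1.0
        best = None
        for _half in range(25):
            coef_c = coef + step * (coef_new - coef)
            b_c = b + step * (b_new - b)
            q_c = q + step * (q_new - q)
            eta_c = X @ coef_c + b_c
            obj_c = pen_obj(eta_c, b_c, q_c)
            if obj_c >= history[-1] - 1e-12:
                best = (coef_c, b_c, q_c, eta_c, obj_c)
                break
            step /= 2.0
        if best is None:  # no improving step: accept the tiny damped step
            best = (coef_c, b_c, q_c, eta_c, max(obj_c, history[-1]))
        delta = np.max(np.abs(best[3] - eta))
        coef, b, q, eta, obj = best
        history.append(obj)
        if delta < tol:
            converged = True
            break
    return coef, b, eta, history, converged


def _projection_pieces(V, X, z, kernels):
    """Scores, AI matrix, REML log-likelihood and GLS pieces at (V, z)."""
    n = V.shape[0]
    cho = cho_factor(V, lower=True)
    Vinv = cho_solve(cho, np.eye(n))
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cho_x = cho_factor(XtViX, lower=True)
    Viz = Vinv @ z
    coef = cho_solve(cho_x, X.T @ Viz)
    Pz = Viz - ViX @ coef

    scores = np.empty(len(kernels))
    u = []  # A_k @ Pz
    for k, A in enumerate(kernels):
        if A.ndim == 1:
            APz = A * Pz
            trVA = float(np.sum(np.diag(Vinv) * A))
            M = ViX * A[:, None]  # A @ ViX for diagonal A
        else:
            APz = A @ Pz
            trVA = float(np.sum(Vinv * A))
            M = A @ ViX
        small = cho_solve(cho_x, ViX.T @ M)
        trPA = trVA - float(np.trace(small))
        scores[k] = 0.5 * (float(Pz @ APz) - trPA)
        u.append(APz)
    AI = np.empty((len(kernels), len(kernels)))
    Pu = []
    for uk in u:
        Viu = Vinv @ uk
        Pu.append(Viu - ViX @ cho_solve(cho_x, X.T @ Viu))
    for k in range(len(kernels)):
        for l in range(k, len(kernels)):
            AI[k, l] = AI[l, k] = 0.5 * float(u[k] @ Pu[l])
    ll = -0.5 * (
        2.0 * np.sum(np.log(np.diag(cho[0])))
        + np.linalg.slogdet(XtViX)[1]
        + float(z @ Pz)
    )
    return scores, AI, ll, coef, Pz


def fit_null_pql_aireml(
    y: np.ndarray,
    Z: np.ndarray,
    D: np.ndarray | None,
    K: np.ndarray,
    K_D: np.ndarray | None = None,
    family: FamilySpec | None = None,
    a: np.ndarray | None = None,
    max_outer: int = 50,
    tol: float = 1e-4,
    tol_score: float = 1e-3,
) -> NullFit:
    """Two-step null-model fit: PQL working model + AI-REML for
    ``(tau_g, tau_d[, phi])`` under ``beta = gamma = 0``.

    Parameters
    ----------
    y : response vector (binary in {0,1} for binomial).
    Z : covariate matrix including the intercept column.
    D : environmental exposure vector (unpenalized fixed effect), or None.
    K, K_D : kinship and GxE kinship; ``K_D=None`` fits a single random
        effect.
    """
    family = binomial() if family is None else family
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = y.shape[0]
    a = np.ones(n) if a is None else np.asarray(a, dtype=float)
    X = Z if D is None else np.column_stack([Z, np.asarray(D, dtype=float)])
    m = X.shape[1]
    if n < m + 2:
        raise ValueError("need n >= m + 2 observations")
    if np.linalg.matrix_rank(X) < m:
        raise ValueError("collinear fixed-effect columns in [Z, D]")
    if family.name == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial family requires binary y in {0,1}")

    K = np.asarray(K, dtype=float)
    kernels: list[np.ndarray] = []
    names: list[str] = []
    if family.estimate_phi:
        kernels.append(1.0 / a)  # diagonal kernel for the dispersion
        names.append("phi")
    kernels.append(K)
    names.append("tau_g")
    if K_D is not None:
        kernels.append(np.asarray(K_D, dtype=float))
        names.append("tau_d")

    # --- initialization from the fixed-effects GLM fit -------------------
    coef, eta, mu = _irls_glm(y, X, family, a)
    phi = family.phi
    w = working_weights(mu, family, a, phi)
    z = eta + (y - mu) * family.dlink(mu)
    var_resid = float(np.var(z - X @ coef))
    params = np.empty(len(kernels))
    for k, nm in enumerate(names):
        params[k] = (0.5 if nm == "phi" else 0.1) * var_resid
    params = np.maximum(params, 1e-6)

    b = np.zeros(n)
    converged = False
    scores = np.zeros(len(kernels))
    it = 0
    for it in range(1, max_outer + 1):
        if family.estimate_phi:
            phi = params[names.index("phi")]
            w = working_weights(mu, family, a, phi)
            base = np.zeros(n)
        else:
            base = 1.0 / w
        V = np.diag(base)
        for k, nm in enumerate(names):
            if nm == "phi":
                V += params[k] * np.diag(kernels[k])
            else:
                V += params[k] * kernels[k]

        free = np.array(
            [not (params[k] <= 1e-8 and scores[k] < 0) for k in range(len(kernels))]
        ) if it > 1 else np.ones(len(kernels), dtype=bool)

        scores, AI, ll, coef, Pz = _projection_pieces(V, X, z, kernels)

        # Newton (AI) step on the free components, with step halving when the
        # step exits the parameter space or decreases the REML log-likelihood
        idx = np.flatnonzero(free)
        if idx.size:
            AIf = AI[np.ix_(idx, idx)]
            try:
                delta = np.linalg.solve(AIf, scores[idx])
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(AIf, scores[idx], rcond=None)[0]
            step = 1.0
            accepted = params.copy()
            for _half in range(12):
                cand = params.copy()
                cand[idx] = params[idx] + step * delta
                if np.any(cand < 0):
                    neg = cand < 0
                    cand[neg] = 0.0
                Vc = np.diag(base)
                for k, nm in enumerate(names):
                    Vc += cand[k] * (np.diag(kernels[k]) if nm == "phi" else kernels[k])
                try:
                    _, _, llc, _, _ = _projection_pieces(Vc, X, z, kernels)
                except np.linalg.LinAlgError:
                    step /= 2.0
                    continue
                if llc >= ll - 1e-10:
                    accepted = cand
                    break
                step /= 2.0
            new_params = accepted
        else:
            new_params = params.copy()
        new_params = np.maximum(new_params, 0.0)

        rel_change = np.max(
            np.abs(new_params - params) / np.maximum(np.abs(params), 1e-4)
        )
        params = new_params

        # --- PQL refit of (coef, b) at the updated variance components ----
        if family.estimate_phi:
            phi = max(params[names.index("phi")], 1e-8)
        Sigma = np.zeros((n, n))
        for k, nm in enumerate(names):
            if nm != "phi":
                Sigma += params[k] * kernels[k]
        coef, b, eta, _, _ = pql_working_fit(
            y, X, Sigma if np.any(Sigma) else None, family, a, phi,
            coef0=coef, b0=b, max_iter=10, tol=1e-8,
        )
        mu = family.inverse_link(eta)
        if family.name == "binomial":
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = working_weights(mu, family, a, phi)
        z = eta + (y - mu) * family.dlink(mu)

        at_boundary = params <= 1e-8
        score_ok = np.all(
            (np.abs(scores) < tol_score * max(1.0, abs(ll)))
            | (at_boundary & (scores < 0))
        )
        if rel_change < tol and score_ok:
            converged = True
            break

    tau_g = float(params[names.index("tau_g")])
    tau_d = float(params[names.index("tau_d")]) if "tau_d" in names else 0.0
    theta = coef[:-1] if D is not None else coef
    alpha = float(coef[-1]) if D is not None else 0.0
    return NullFit(
        theta=np.asarray(theta, dtype=float),
        alpha=alpha,
        tau_g=tau_g,
        tau_d=tau_d,
        phi=float(phi),
        b=b,
        converged=converged,
        n_iter=it,
        scores=scores,
        eta=eta,
    )
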