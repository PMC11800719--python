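"""Scikit-learn style estimators: the primary user-facing API.

``PQLVarianceComponents`` estimates the null-model variance components;
``GxEMixedLassoPath`` fits the full sparse group lasso regularization path
of the penalized quasi-likelihood mixed model; ``GxEMixedLassoCV`` adds
cross-validated selection of ``(lambda, rho)`` and prediction of case
probabilities.  All follow the fit/predict convention with trailing
underscores on fitted attributes and compose with ``sklearn``
``get_params``/``set_params`` and ``clone``.

The genotype matrix plays the role of ``X``; exposure, covariates and
kinship matrices are passed as fit keyword arguments (they are per-sample
side information, like ``sample_weight``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import kinship as ks
from .families import FamilySpec, binomial
from .kinship import GenotypePanel, SpectralBasis
from .model_selection import CVResult, cross_validate, predict_probabilities
from .null_model import NullFit, fit_null_pql_aireml
from .penalized_path import (
    PathData,
    PenaltyConfig,
    default_penalty_config,
    fit_null_state,
    solution_path,
)

__all__ = ["PQLVarianceComponents", "GxEMixedLassoPath", "GxEMixedLassoCV"]


def _as_design(G, expect_standardized: bool):
    """Accept a GenotypePanel or raw / standardized matrix."""
    if isinstance(G, GenotypePanel):
        return ks.standardize_genotypes(G)
    G = np.asarray(G, dtype=float)
    if not expect_standardized and np.nanmax(G) <= 2 and np.nanmin(G) >= 0:
        # raw allele counts: standardize through a panel for validation
        return ks.standardize_genotypes(GenotypePanel(G))
    return G


def _with_intercept(Z, n):
    if Z is None:
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    if not np.any(np.all(Z == Z[0], axis=0) & (Z[0] != 0)):
        Z = np.column_stack([np.ones(n), Z])
    return Z


class PQLVarianceComponents(BaseEstimator):
    """Null-model variance-component estimator (PQL + AI-REML).

    Parameters
    ----------
    family : FamilySpec, default binomial (logit link).
    max_iter, tol, tol_score : outer-loop controls of the AI-REML fit.
    stabilize_eps : jitter added to a rank-deficient kinship matrix.

    Attributes (after fit)
    ----------------------
    theta_, alpha_ : covariate and exposure fixed effects.
    tau_g_, tau_d_, phi_ : variance components and dispersion.
    b_ : predicted random-effect vector.
    null_fit_ : the underlying :class:`NullFit`.
    """

    def __init__(
        self,
        family: FamilySpec | None = None,
        max_iter: int = 50,
        tol: float = 1e-4,
        tol_score: float = 1e-3,
        stabilize_eps: float = 1e-4,
    ):
        self.family = family
        self.max_iter = max_iter
        self.tol = tol
        self.tol_score = tol_score
        self.stabilize_eps = stabilize_eps

    def fit(self, X, y, *, exposure=None, K=None, K_D=None):
        """Fit with covariates ``X`` (intercept added if absent), binary
        response ``y``, optional exposure and kinship matrices."""
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        Z = _with_intercept(X, n)
        if K is None:
            raise ValueError("the null model requires a kinship matrix K")
        K = np.asarray(K, dtype=float)
        K, _ = ks.ensure_positive_definite(K, eps=self.stabilize_eps)
        family = binomial() if self.family is None else self.family
        fit = fit_null_pql_aireml(
            y, Z, exposure, K, K_D, family=family,
            max_outer=self.max_iter, tol=self.tol, tol_score=self.tol_score,
        )
        self.null_fit_ = fit
        self.theta_ = fit.theta
        self.alpha_ = fit.alpha
        self.tau_g_ = fit.tau_g
        self.tau_d_ = fit.tau_d
        self.phi_ = fit.phi
        self.b_ = fit.b
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.K_ = K
        self.K_D_ = None if K_D is None else np.asarray(K_D, dtype=float)
        return self


class GxEMixedLassoPath(BaseEstimator):
    """Sparse group lasso path for hierarchical GxE selection in a
    logistic (or gaussian) mixed model.

    The model couples every SNP main effect ``beta_j`` with its
    gene-environment interaction ``gamma_j`` in one penalized group; the
    composite penalty ``(1-rho) lam ||(beta_j, gamma_j)||_2 +
    rho lam |gamma_j|`` enforces strong hierarchy (an interaction is
    selected only together with its main effect).  Population structure
    and shared exposure enter through the two-kinship random effect whose
    variance components come from the null-model fit.

    Attributes (after fit)
    ----------------------
    null_fit_ : NullFit from the first step.
    basis_ : SpectralBasis of ``tau_g K + tau_d K_D``.
    penalty_ : PenaltyConfig actually used (data-derived lambda grid).
    path_ : list of PathPoint over the (rho, lambda) grid.
    lambda_max_ : largest lambda of the grid (zero-support boundary).
    """

    def __init__(
        self,
        family: FamilySpec | None = None,
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        n_rho: int = 10,
        rho_max: float = 0.9,
        interactions: bool = True,
        use_gxe_kinship: bool = True,
        stabilize_eps: float = 1e-4,
        max_outer: int = 50,
        max_inner: int = 100,
        tol_inner: float = 1e-7,
        tol_outer: float = 1e-6,
    ):
        self.family = family
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.n_rho = n_rho
        self.rho_max = rho_max
        self.interactions = interactions
        self.use_gxe_kinship = use_gxe_kinship
        self.stabilize_eps = stabilize_eps
        self.max_outer = max_outer
        self.max_inner = max_inner
        self.tol_inner = tol_inner
        self.tol_outer = tol_outer

    # ------------------------------------------------------------------
    def _prepare(self, G, y, exposure, covariates, K, K_D, kinship_panel):
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        G_std = _as_design(G, expect_standardized=False)
        if G_std.shape[0] != n:
            raise ValueError("G and y have inconsistent sample counts")
        Z = _with_intercept(covariates, n)
        D = None if exposure is None else np.asarray(exposure, float).ravel()
        if K is None:
            if kinship_panel is None:
                raise ValueError("provide K or a kinship_panel to build it")
            K = ks.compute_grm(_as_design(kinship_panel, False))
        K = np.asarray(K, dtype=float)
        K, _ = ks.ensure_positive_definite(K, eps=self.stabilize_eps)
        if self.use_gxe_kinship and K_D is None and D is not None:
            K_D = ks.build_gxe_kinship(K, D, kind="binary")
        family = binomial() if self.family is None else self.family
        data = PathData(
            y=y, Z=Z, D=D, G_std=G_std, family=family,
            interactions=self.interactions and D is not None,
        )
        return data, K, (None if not self.use_gxe_kinship else K_D)

    def fit(self, G, y, *, exposure=None, covariates=None, K=None, K_D=None,
            kinship_panel=None, penalty: PenaltyConfig | None = None):
        data, K, K_D = self._prepare(
            G, y, exposure, covariates, K, K_D, kinship_panel
        )
        null = fit_null_pql_aireml(
            data.y, data.Z, data.D, K, K_D, family=data.family
        )
        tau_g = max(null.tau_g, 1e-8)  # keep the covariance invertible
        basis = ks.spectral_decompose(tau_g, null.tau_d, K, K_D)
        null_state = fit_null_state(data, basis, null)
        if penalty is None:
            penalty = default_penalty_config(
                data, basis, null_state,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                n_rho=self.n_rho, rho_max=self.rho_max,
            )
        self.path_ = solution_path(
            data, null, basis, penalty, null_state=null_state,
            max_outer=self.max_outer, max_inner=self.max_inner,
            tol_inner=self.tol_inner, tol_outer=self.tol_outer,
        )
        self.data_ = data
        self.null_fit_ = null
        self.basis_ = basis
        self.penalty_ = penalty
        self.lambda_max_ = penalty.lambda_max
        self.K_ = K
        self.K_D_ = K_D
        return self


class GxEMixedLassoCV(GxEMixedLassoPath):
    """Cross-validated variant: selects ``(lambda, rho)`` by K-fold CV and
    refits the final model on all samples.

    Additional attributes after fit: ``cv_result_``, ``lambda_``, ``rho_``,
    ``coef0_`` (covariates + exposure), ``beta_``, ``gamma_``, ``delta_``.
    """

    def __init__(
        self,
        family: FamilySpec | None = None,
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        n_rho: int = 10,
        rho_max: float = 0.9,
        interactions: bool = True,
        use_gxe_kinship: bool = True,
        stabilize_eps: float = 1e-4,
        max_outer: int = 50,
        max_inner: int = 100,
        tol_inner: float = 1e-7,
        tol_outer: float = 1e-6,
        cv: int = 10,
        metric: str = "deviance",
        random_state: int = 0,
    ):
        super().__init__(
            family=family, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, n_rho=n_rho, rho_max=rho_max,
            interactions=interactions, use_gxe_kinship=use_gxe_kinship,
            stabilize_eps=stabilize_eps, max_outer=max_outer,
            max_inner=max_inner, tol_inner=tol_inner, tol_outer=tol_outer,
        )
        self.cv = cv
        self.metric = metric
        self.random_state = random_state

    def fit(self, G, y, *, exposure=None, covariates=None, K=None, K_D=None,
            kinship_panel=None, penalty: PenaltyConfig | None = None):
        data, K, K_D = self._prepare(
            G, y, exposure, covariates, K, K_D, kinship_panel
        )
        null = fit_null_pql_aireml(
            data.y, data.Z, data.D, K, K_D, family=data.family
        )
        tau_g = max(null.tau_g, 1e-8)
        basis = ks.spectral_decompose(tau_g, null.tau_d, K, K_D)
        null_state = fit_null_state(data, basis, null)
        if penalty is None:
            penalty = default_penalty_config(
                data, basis, null_state,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                n_rho=self.n_rho, rho_max=self.rho_max,
            )
        cvres: CVResult = cross_validate(
            data, null, basis, penalty, folds=self.cv, metric=self.metric,
            seed=self.random_state,
            max_outer=self.max_outer, max_inner=self.max_inner,
            tol_inner=self.tol_inner, tol_outer=self.tol_outer,
        )
        self.data_ = data
        self.null_fit_ = null
        self.basis_ = basis
        self.penalty_ = penalty
        self.lambda_max_ = penalty.lambda_max
        self.K_ = K
        self.K_D_ = K_D
        self.cv_result_ = cvres
        self.lambda_ = cvres.best_lambda
        self.rho_ = cvres.best_rho
        st = cvres.final_state
        self.coef0_ = st.coef0
        self.beta_ = st.beta
        self.gamma_ = st.gamma
        self.delta_ = st.delta
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, G, *, exposure=None, covariates=None,
                      K_cross=None, K_D_cross=None):
        """Case probabilities for new individuals (random effect transfers
        through the conditional mean when cross-kinship blocks are given)."""
        G_std = _as_design(G, expect_standardized=True)
        n_new = G_std.shape[0]
        Z = _with_intercept(covariates, n_new)
        D = None if exposure is None else np.asarray(exposure, float).ravel()
        p1 = predict_probabilities(
            self.cv_result_.final_state, self.null_fit_, Z, D, G_std,
            family=self.data_.family,
            K_cross=K_cross, K_D_cross=K_D_cross,
            K_train=self.K_, K_D_train=self.K_D_,
        )
        return np.column_stack([1.0 - p1, p1])

    def predict(self, G, **kwargs):
        return (self.predict_proba(G, **kwargs)[:, 1] >= 0.5).astype(int)
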