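"""Cross-validation over the (lambda, rho) grid and out-of-sample
prediction.

Folds are stratified by case status.  Following the two-step philosophy,
the variance components and the spectral basis are estimated once on the
full data and reused in every fold; each fold refits the regularization
path on its training rows only (the training rows of the eigenvector
matrix enter the random-effect term, so held-out individuals receive their
random-effect prediction through the shared basis).  The default
validation loss is the binomial deviance; AUC is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .families import FamilySpec
from .kinship import SpectralBasis
from .null_model import NullFit
from .penalized_path import (
    CoefficientState,
    PathData,
    PenaltyConfig,
    fit_path_point,
    fit_null_state,
    default_penalty_config,
)

__all__ = ["CVResult", "cross_validate", "predict_probabilities", "auc",
           "stratified_folds"]


@dataclass
class CVResult:
    """Cross-validation surface and the selected tuning pair."""

    lambda_grid: np.ndarray
    rho_grid: np.ndarray
    mean_metric: np.ndarray  # (n_lambda, n_rho)
    se_metric: np.ndarray
    best_lambda: float
    best_rho: float
    best_index: tuple[int, int]
    final_state: CoefficientState
    fold_assignments: np.ndarray
    metric: str = "deviance"


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties count 1/2)."""
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _deviance(y: np.ndarray, prob: np.ndarray) -> np.ndarray:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return -2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob))


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified by the binary outcome, seeded."""
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def cross_validate(
    data: PathData,
    null_fit: NullFit,
    basis: SpectralBasis,
    penalty_config: PenaltyConfig | None = None,
    folds: int = 10,
    metric: str = "deviance",
    seed: int = 0,
    **point_kwargs,
) -> CVResult:
    """K-fold cross-validation of the whole tuning grid.

    For every fold the path is refit on the training rows (warm starts
    across lambda within each rho sweep) and the validation loss of each
    grid point is computed on the held-out rows.  The selected pair
    minimizes the mean deviance (or maximizes mean AUC); ties resolve to
    the larger lambda, then the smaller rho.  The final model is refit on
    all rows at the selected pair.
    """
    if metric not in ("deviance", "auc"):
        raise ValueError("metric must be 'deviance' or 'auc'")
    if data.family.name != "binomial":
        raise ValueError("cross_validate currently supports binary traits")
    y = data.y
    fold = stratified_folds(y, folds, seed)
    full_null_state = fit_null_state(data, basis, null_fit)
    if penalty_config is None:
        penalty_config = default_penalty_config(data, basis, full_null_state)
    n_lam = penalty_config.lambda_grid.size
    n_rho = penalty_config.rho_grid.size

    fold_metric = np.full((folds, n_lam, n_rho), np.nan)
    for f in range(folds):
        tr = np.flatnonzero(fold != f)
        va = np.flatnonzero(fold == f)
        if np.unique(y[va]).size < 2 and metric == "auc":
            raise ValueError("a fold lost a class; use more data or fewer folds")
        dtr = data.subset(tr)
        dva = data.subset(va)
        null_state_tr = fit_null_state(dtr, basis, null_fit)
        for r, rho in enumerate(penalty_config.rho_grid):
            state = null_state_tr.copy()
            for l, lam in enumerate(penalty_config.lambda_grid):
                pt = fit_path_point(dtr, basis, state, lam, rho, **point_kwargs)
                state = pt.state
                eta_va = _linear_predictor(dva, basis, state)
                prob = dva.family.inverse_link(eta_va)
                if metric == "deviance":
                    fold_metric[f, l, r] = float(np.mean(_deviance(y[va], prob)))
                else:
                    fold_metric[f, l, r] = auc(prob, y[va])

    mean_metric = fold_metric.mean(axis=0)
    se_metric = fold_metric.std(axis=0, ddof=1) / np.sqrt(folds)
    crit = mean_metric if metric == "deviance" else -mean_metric
    best = np.min(crit)
    # ties: larger lambda (smaller row index), then smaller rho
    cand = np.argwhere(crit <= best + 1e-12)
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    li, ri = int(cand[0, 0]), int(cand[0, 1])

    # refit on all data: warm path down to the chosen lambda at chosen rho
    state = full_null_state.copy()
    for lam in penalty_config.lambda_grid[: li + 1]:
        pt = fit_path_point(
            data, basis, state, lam, penalty_config.rho_grid[ri], **point_kwargs
        )
        state = pt.state
    return CVResult(
        lambda_grid=penalty_config.lambda_grid,
        rho_grid=penalty_config.rho_grid,
        mean_metric=mean_metric,
        se_metric=se_metric,
        best_lambda=float(penalty_config.lambda_grid[li]),
        best_rho=float(penalty_config.rho_grid[ri]),
        best_index=(li, ri),
        final_state=state,
        fold_assignments=fold,
        metric=metric,
    )


def _linear_predictor(
    data: PathData, basis: SpectralBasis, state: CoefficientState
) -> np.ndarray:
    """Linear predictor for rows of ``data`` (which may differ from the
    rows the state was fit on) using the shared spectral basis."""
    eta = data.X0 @ state.coef0 + data.U_rows(basis) @ state.delta
    nz_b = np.flatnonzero(state.beta)
    if nz_b.size:
        eta = eta + data.G_std[:, nz_b] @ state.beta[nz_b]
    if data.interactions:
        nz_g = np.flatnonzero(state.gamma)
        if nz_g.size:
            eta = eta + data.C[:, nz_g] @ state.gamma[nz_g]
    return eta


def predict_probabilities(
    final_state: CoefficientState,
    null_fit: NullFit,
    new_Z: np.ndarray,
    new_D: np.ndarray | None,
    new_G_std: np.ndarray,
    family: FamilySpec | None = None,
    K_cross: np.ndarray | None = None,
    K_D_cross: np.ndarray | None = None,
    K_train: np.ndarray | None = None,
    K_D_train: np.ndarray | None = None,
) -> np.ndarray:
    """Case probabilities for external individuals.

    New genotypes must be standardized with the training allele
    frequencies.  When cross-kinship blocks (new x train) are supplied, the
    random effect transfers by the conditional Gaussian mean
    ``b_new = Sigma_cross Sigma_train^{-1} b_tilde`` with
    ``Sigma = tau_g K + tau_d K_D``; otherwise ``b_new = 0``.
    """
    from .families import binomial

    family = binomial() if family is None else family
    new_Z = np.atleast_2d(np.asarray(new_Z, dtype=float))
    new_G_std = np.atleast_2d(np.asarray(new_G_std, dtype=float))
    n_new = new_Z.shape[0]
    p = final_state.beta.shape[0]
    if new_G_std.shape[1] != p:
        raise ValueError(
            f"genotype columns ({new_G_std.shape[1]}) do not match the "
            f"coefficient support ({p})"
        )
    X0 = (
        np.column_stack([new_Z, np.asarray(new_D, dtype=float)])
        if new_D is not None
        else new_Z
    )
    eta = X0 @ final_state.coef0
    nz = np.flatnonzero(final_state.beta)
    if nz.size:
        eta = eta + new_G_std[:, nz] @ final_state.beta[nz]
    nz_g = np.flatnonzero(final_state.gamma)
    if nz_g.size:
        if new_D is None:
            raise ValueError("GEI coefficients present but no exposure given")
        eta = eta + (
            np.asarray(new_D, float)[:, None] * new_G_std[:, nz_g]
        ) @ final_state.gamma[nz_g]

    if K_cross is not None:
        if K_train is None:
            raise ValueError("kinship transfer needs the training kinship")
        Sigma_tr = null_fit.tau_g * np.asarray(K_train, dtype=float)
        Sigma_cross = null_fit.tau_g * np.asarray(K_cross, dtype=float)
        if null_fit.tau_d != 0.0:
            if K_D_train is None or K_D_cross is None:
                raise ValueError("tau_d > 0 requires the GxE kinship blocks")
            Sigma_tr = Sigma_tr + null_fit.tau_d * np.asarray(K_D_train, float)
            Sigma_cross = Sigma_cross + null_fit.tau_d * np.asarray(K_D_cross, float)
        b_new = Sigma_cross @ np.linalg.solve(Sigma_tr, null_fit.b)
        eta = eta + b_new
    return family.inverse_link(eta[:n_new])
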