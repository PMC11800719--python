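"""Sparse group lasso regularization path for the PQL mixed model.

Given null-model variance components and the spectral basis
``U diag(Lambda) U' = tau_g K + tau_d K_D``, this module minimizes, over a
two-dimensional grid of tuning parameters ``(lambda, rho)``,

    Q(Theta, delta) = -sum_i ql_i(eta_i) + delta' Lambda^-1 delta / 2
                      + (1-rho) lambda sum_j ||(beta_j, gamma_j)||_2
                      + rho lambda sum_j |gamma_j|

where ``eta = Z theta + D alpha + Gs beta + (D * Gs) gamma + U delta``,
``Gs`` is the standardized genotype matrix and ``delta = U' b`` the rotated
random-effect vector.  The composite penalty induces strong hierarchy: a
GEI coefficient ``gamma_j`` can be nonzero only if the group ``(beta_j,
gamma_j)`` is selected, hence only together with its main effect.  The
exposure effect ``alpha`` and the covariates are never penalized.

The solver is a proximal Newton method: the quasi-likelihood is replaced by
its weighted least-squares expansion with weights frozen within each outer
step, and the quadratic subproblem is solved by block coordinate descent
over the per-SNP groups (closed-form sparse-group prox on a majorized
Newton step) together with exact updates of the unpenalized coefficients
and a generalized ridge solve for ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._solver import bcd_cycles
from .families import FamilySpec, binomial
from .kinship import SpectralBasis
from .null_model import NullFit

__all__ = [
    "PathData",
    "PenaltyConfig",
    "CoefficientState",
    "PathPoint",
    "prox_sparse_group",
    "objective_value",
    "update_random_effects",
    "bcd_fixed_update",
    "compute_lambda_max",
    "solution_path",
    "fit_path_point",
    "kkt_residuals",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class PathData:
    """Design bundle for the penalized fit.

    ``Z`` must include the intercept column.  ``G_std`` holds standardized
    genotypes; the interaction columns ``D * G_std`` are formed on demand
    and share the genotype standardization.  ``interactions=False`` drops
    the GEI part entirely (groups of size one, plain group lasso on beta).
    """

    y: np.ndarray
    Z: np.ndarray
    D: np.ndarray | None
    G_std: np.ndarray
    family: FamilySpec = field(default_factory=binomial)
    a: np.ndarray | None = None
    interactions: bool = True
    rows: np.ndarray | None = None  # indices into the spectral basis rows

    def U_rows(self, basis: SpectralBasis) -> np.ndarray:
        """Rows of the eigenvector matrix aligned with this data bundle."""
        if self.rows is None:
            if basis.n != self.n:
                raise ValueError(
                    "basis size does not match data; pass row indices"
                )
            return basis.U
        return basis.U[self.rows]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.G_std = np.asarray(self.G_std, dtype=float)
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)
        if self.interactions and self.D is None:
            raise ValueError("interaction columns require an exposure D")
        n = self.y.shape[0]
        self.X0 = (
            np.column_stack([self.Z, self.D]) if self.D is not None else self.Z
        )
        if self.X0.shape[0] != n or self.G_std.shape[0] != n:
            raise ValueError("inconsistent row counts")
        # column-major storage: the solver works column by column
        self.G_std = np.asfortranarray(self.G_std)
        self.C = (
            np.asfortranarray(self.D[:, None] * self.G_std)
            if self.interactions else None
        )
        if self.a is None:
            self.a = np.ones(n)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.G_std.shape[1]

    def subset(self, rows: np.ndarray) -> "PathData":
        rows = np.asarray(rows)
        parent = np.arange(self.y.shape[0]) if self.rows is None else self.rows
        return PathData(
            y=self.y[rows],
            Z=self.Z[rows],
            D=None if self.D is None else self.D[rows],
            G_std=self.G_std[rows],
            family=self.family,
            a=self.a[rows],
            interactions=self.interactions,
            rows=parent[rows],
        )


@dataclass
class PenaltyConfig:
    """Tuning-parameter grids: 50 log10-spaced lambdas down to
    ``0.01 * lambda_max`` and 10 rho values evenly spaced on [0, 0.9]."""

    lambda_grid: np.ndarray
    rho_grid: np.ndarray
    lambda_max: float

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        if self.lambda_grid.size == 0 or self.rho_grid.size == 0:
            raise ValueError("empty tuning grid")
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        if np.any((self.rho_grid < 0) | (self.rho_grid >= 1)):
            raise ValueError("rho must lie in [0, 1)")

    @classmethod
    def default(
        cls,
        lambda_max: float,
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        n_rho: int = 10,
        rho_max: float = 0.9,
    ) -> "PenaltyConfig":
        lam = np.logspace(
            np.log10(lambda_max),
            np.log10(lambda_max * lambda_min_ratio),
            n_lambda,
        )
        rho = np.linspace(0.0, rho_max, n_rho)
        return cls(lambda_grid=lam, rho_grid=rho, lambda_max=float(lambda_max))


@dataclass
class CoefficientState:
    """Current coefficients and rotated random effects of the path fit."""

    coef0: np.ndarray  # unpenalized: covariates (incl. intercept) then alpha
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray  # rotated random effects, delta = U' b
    eta: np.ndarray

    def copy(self) -> "CoefficientState":
        return CoefficientState(
            self.coef0.copy(),
            self.beta.copy(),
            self.gamma.copy(),
            self.delta.copy(),
            self.eta.copy(),
        )

    @property
    def theta(self) -> np.ndarray:
        return self.coef0[:-1]

    @property
    def alpha(self) -> float:
        return float(self.coef0[-1])

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        return np.flatnonzero(self.beta), np.flatnonzero(self.gamma)


@dataclass
class PathPoint:
    """One fitted model on the (lambda, rho) grid."""

    lam: float
    rho: float
    state: CoefficientState
    objective: float
    size_main: int
    size_gei: int
    n_outer: int
    n_inner: int
    converged: bool


# ----------------------------------------------------------------------
# proximal operator
# ----------------------------------------------------------------------
def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def prox_sparse_group(
    u_beta: float, u_gamma: float, t: float, lam: float, rho: float
) -> tuple[float, float]:
    """Closed-form proximal operator of the hierarchy-inducing penalty
    ``t * [(1-rho) lam ||(beta, gamma)||_2 + rho lam |gamma|]``.

    Soft-threshold the GEI coordinate at ``t rho lam``, then group-shrink
    the pair at ``t (1-rho) lam``.  The group shrinkage can only zero both
    coordinates together, so a surviving ``gamma`` implies a surviving
    ``beta`` whenever ``u_beta != 0``: strong hierarchy.
    """
    if t <= 0:
        raise ValueError("step size t must be positive")
    g = _soft(u_gamma, t * rho * lam)
    norm = np.hypot(u_beta, g)
    if norm == 0.0:
        return 0.0, 0.0
    scale = max(0.0, 1.0 - t * (1.0 - rho) * lam / norm)
    return scale * u_beta, scale * g




# ----------------------------------------------------------------------
# objective and pieces
# ----------------------------------------------------------------------
def _eta_of(data: PathData, basis: SpectralBasis, state: CoefficientState):
    act_b = np.flatnonzero(state.beta)
    act_g = np.flatnonzero(state.gamma) if data.interactions else np.empty(0, int)
    eta = data.X0 @ state.coef0 + data.U_rows(basis) @ state.delta
    if act_b.size:
        eta = eta + data.G_std[:, act_b] @ state.beta[act_b]
    if act_g.size:
        eta = eta + data.C[:, act_g] @ state.gamma[act_g]
    return eta


def penalty_value(beta, gamma, lam, rho) -> float:
    return float(
        (1 - rho) * lam * np.sum(np.hypot(beta, gamma))
        + rho * lam * np.sum(np.abs(gamma))
    )


def objective_value(
    state: CoefficientState,
    data: PathData,
    Lambda: np.ndarray,
    lam: float,
    rho: float,
    family: FamilySpec | None = None,
) -> float:
    """Penalized PQL objective ``Q = -sum ql + delta' Lambda^-1 delta / 2
    + penalty`` at the given state."""
    family = data.family if family is None else family
    gamma = state.gamma if data.interactions else np.zeros_like(state.beta)
    nql = family.neg_quasi_loglik(data.y, state.eta, data.a)
    ridge = 0.5 * float(np.sum(state.delta**2 / Lambda))
    return nql + ridge + penalty_value(state.beta, gamma, lam, rho)


def update_random_effects(
    state: CoefficientState,
    data: PathData,
    basis: SpectralBasis,
    family: FamilySpec | None = None,
    w: np.ndarray | None = None,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Generalized ridge WLS update of the rotated random effects:
    solves ``(U' W U + Lambda^-1) delta = U' W r`` where ``r`` is the
    working residual with the fixed effects held at their current values.
    """
    family = data.family if family is None else family
    U = data.U_rows(basis)
    if w is None or z is None:
        mu = family.inverse_link(state.eta)
        if family.name == "binomial":
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
        from .null_model import working_weights

        w = working_weights(mu, family, data.a, family.phi)
        z = state.eta + (data.y - mu) * family.dlink(mu)
    eta_fixed = state.eta - U @ state.delta
    r = z - eta_fixed
    M = U.T @ (w[:, None] * U)
    M[np.diag_indices_from(M)] += 1.0 / basis.Lambda
    rhs = U.T @ (w * r)
    cho = cho_factor(M, lower=True)
    return cho_solve(cho, rhs)


# ----------------------------------------------------------------------
# single path-point solver (proximal Newton with BCD inner loop)
# ----------------------------------------------------------------------
def fit_path_point(
    data: PathData,
    basis: SpectralBasis,
    state: CoefficientState,
    lam: float,
    rho: float,
    max_outer: int = 50,
    max_inner: int = 100,
    tol_inner: float = 1e-7,
    tol_outer: float = 1e-6,
    penalized: bool = True,
) -> PathPoint:
    """Fit one (lambda, rho) point, warm-starting from ``state``.

    With ``penalized=False`` only the unpenalized coefficients and the
    random effects are iterated (the null-covariate fit used at
    ``lambda >= lambda_max`` and for the lambda-max gradient).
    """
    family = data.family
    Lam = basis.Lambda
    n, p = data.n, data.p
    st = state.copy()
    st.eta = _eta_of(data, basis, st)

    obj = objective_value(st, data, Lam, lam, rho)
    n_inner_total = 0
    converged = False
    active = set(np.flatnonzero(np.hypot(st.beta, st.gamma)).tolist()) if penalized else set()

    for outer in range(1, max_outer + 1):
        prev_obj = obj
        prev = st.copy()

        # ---- freeze weights and working response at the current state ----
        mu = family.inverse_link(st.eta)
        if family.name == "binomial":
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
        from .null_model import working_weights

        w = working_weights(mu, family, data.a, family.phi)
        z = st.eta + (data.y - mu) * family.dlink(mu)

        # ---- generalized ridge update of the rotated random effects ------
        st.delta = update_random_effects(st, data, basis, family, w=w, z=z)
        st.eta = _eta_of(data, basis, st)

        # ---- BCD on the quadratic model for the fixed effects ------------
        res = z - st.eta
        X0 = data.X0
        WX0 = w[:, None] * X0
        A0inv = np.linalg.inv(X0.T @ WX0)
        has_inter = data.interactions
        if penalized:
            hbb_all = np.einsum("i,ij->j", w, data.G_std**2)
            if has_inter:
                hgg_all = np.einsum("i,ij->j", w, data.C**2)
                hbg_all = np.einsum("i,ij,ij->j", w, data.G_std, data.C)
            else:
                hgg_all = np.zeros(p)
                hbg_all = np.zeros(p)
            Cmat = data.C if has_inter else data.G_std  # dummy when absent

        wres = w * res  # maintained alongside res
        inner = 0
        while True:
            # iterate the unpenalized block and the active groups jointly
            # until the quadratic subproblem is stable on the active set
            if penalized:
                active_idx = np.array(sorted(active), dtype=np.int64)
            else:
                active_idx = np.empty(0, dtype=np.int64)
            cycles, _chg = bcd_cycles(
                X0, A0inv, data.G_std, Cmat if penalized else data.G_std,
                has_inter and penalized, w, res, wres,
                st.coef0, st.beta, st.gamma, active_idx,
                hbb_all if penalized else np.zeros(p),
                hbg_all if penalized else np.zeros(p),
                hgg_all if penalized else np.zeros(p),
                float(lam), float(rho), tol_inner, max_inner,
            )
            inner += cycles
            if penalized:
                active = {
                    j for j in active if st.beta[j] != 0.0 or st.gamma[j] != 0.0
                }
            if not penalized:
                break

            # full vectorized KKT sweep over inactive groups
            gB = -(data.G_std.T @ wres)
            gG = -(data.C.T @ wres) if data.interactions else np.zeros(p)
            inact = np.ones(p, dtype=bool)
            if active:
                inact[list(active)] = False
            sg = np.maximum(np.abs(gG) - rho * lam, 0.0)
            viol = np.hypot(gB, sg) > (1 - rho) * lam * (1 + 1e-9) + 1e-12
            viol &= inact
            if np.any(viol):
                active |= set(np.flatnonzero(viol).tolist())
                continue
            break

        st.eta = _eta_of(data, basis, st)
        obj = objective_value(st, data, Lam, lam, rho)
        n_inner_total += inner

        # ---- safeguard: damp the proximal Newton step if Q increased -----
        if obj > prev_obj + 1e-10:
            step = 0.5
            for _half in range(20):
                cand = CoefficientState(
                    prev.coef0 + step * (st.coef0 - prev.coef0),
                    prev.beta + step * (st.beta - prev.beta),
                    prev.gamma + step * (st.gamma - prev.gamma),
                    prev.delta + step * (st.delta - prev.delta),
                    prev.eta,
                )
                cand.eta = _eta_of(data, basis, cand)
                obj_c = objective_value(cand, data, Lam, lam, rho)
                if obj_c <= prev_obj + 1e-10:
                    st, obj = cand, obj_c
                    active = set(
                        np.flatnonzero(np.hypot(st.beta, st.gamma)).tolist()
                    )
                    break
                step /= 2.0
            else:
                st, obj = prev, prev_obj  # give up on this outer step

        rel = abs(prev_obj - obj) / max(1.0, abs(prev_obj))
        if rel < tol_outer and outer > 1:
            converged = True
            break

    size_main = int(np.count_nonzero(st.beta))
    size_gei = int(np.count_nonzero(st.gamma)) if data.interactions else 0
    return PathPoint(
        lam=float(lam),
        rho=float(rho),
        state=st,
        objective=float(obj),
        size_main=size_main,
        size_gei=size_gei,
        n_outer=outer,
        n_inner=n_inner_total,
        converged=converged,
    )


def bcd_fixed_update(
    state: CoefficientState,
    data: PathData,
    lam: float,
    rho: float,
    family: FamilySpec | None = None,
    basis: SpectralBasis | None = None,
    **kwargs,
) -> CoefficientState:
    """One full proximal-Newton cycle on the fixed effects (delta held
    fixed): convenience wrapper over the path-point engine with a single
    outer iteration and no random-effect refresh."""
    if basis is None:
        raise ValueError("bcd_fixed_update requires the spectral basis")
    pt = fit_path_point(
        data, basis, state, lam, rho, max_outer=1, penalized=True, **kwargs
    )
    return pt.state


# ----------------------------------------------------------------------
# lambda max
# ----------------------------------------------------------------------
def _null_gradient(
    data: PathData, basis: SpectralBasis, null_state: CoefficientState
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of -sum ql w.r.t. (beta_j, gamma_j) at the null-covariate
    solution: for canonical links, ``-X_j' (y - mu) a / phi``."""
    family = data.family
    mu = family.inverse_link(null_state.eta)
    r = (data.y - mu) * data.a / family.phi
    gB = -(data.G_std.T @ r)
    gG = -(data.C.T @ r) if data.interactions else np.zeros(data.p)
    return gB, gG


def fit_null_state(
    data: PathData, basis: SpectralBasis, null_fit: NullFit | None = None
) -> CoefficientState:
    """Weights-converged fit with zero penalized support (covariates,
    exposure and random effects only)."""
    n, p = data.n, data.p
    coef0 = np.zeros(data.X0.shape[1])
    delta = np.zeros(basis.n)
    if null_fit is not None:
        m = null_fit.theta.shape[0]
        coef0[:m] = null_fit.theta
        if data.D is not None:
            coef0[-1] = null_fit.alpha
        if null_fit.b.shape[0] == basis.n:
            delta = basis.U.T @ null_fit.b
    state = CoefficientState(
        coef0=coef0,
        beta=np.zeros(p),
        gamma=np.zeros(p),
        delta=delta,
        eta=np.zeros(n),
    )
    pt = fit_path_point(
        data, basis, state, lam=0.0, rho=0.0, penalized=False,
        max_outer=100, tol_outer=1e-10,
    )
    return pt.state


def compute_lambda_max(
    null_state: CoefficientState,
    data: PathData,
    rho: float,
    basis: SpectralBasis,
) -> float:
    """Smallest lambda at which every group satisfies the zero-solution
    subgradient condition ``||(grad_beta_j, soft(grad_gamma_j, rho*lam))||_2
    <= (1-rho) * lam``; closed form at ``rho = 0``, bisection otherwise."""
    gB, gG = _null_gradient(data, basis, null_state)
    if rho == 0.0:
        lam = float(np.max(np.hypot(gB, gG)))
        return lam
    hi = float(np.max(np.hypot(gB, gG))) / (1.0 - rho)
    if hi == 0.0:
        import warnings

        warnings.warn("all penalized gradients are zero; lambda_max = 0")
        return 0.0
    lo = 0.0

    def satisfied(lam: float) -> bool:
        sg = np.maximum(np.abs(gG) - rho * lam, 0.0)
        return bool(np.all(np.hypot(gB, sg) <= (1.0 - rho) * lam))

    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if satisfied(mid):
            hi = mid
        else:
            lo = mid
    return hi  # upper bracket: the condition is guaranteed to hold


# ----------------------------------------------------------------------
# full path
# ----------------------------------------------------------------------
def default_penalty_config(
    data: PathData,
    basis: SpectralBasis,
    null_state: CoefficientState,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    n_rho: int = 10,
    rho_max: float = 0.9,
) -> PenaltyConfig:
    """Data-derived grids; lambda_max is the largest lambda_max over the
    rho grid so a single lambda grid is shared by every rho sweep."""
    rho_grid = np.linspace(0.0, rho_max, n_rho)
    lam_max = max(
        compute_lambda_max(null_state, data, r, basis) for r in rho_grid
    )
    return PenaltyConfig.default(
        lam_max, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        n_rho=n_rho, rho_max=rho_max,
    )


def solution_path(
    data: PathData,
    null_fit: NullFit,
    basis: SpectralBasis,
    penalty_config: PenaltyConfig | None = None,
    null_state: CoefficientState | None = None,
    **point_kwargs,
) -> list[PathPoint]:
    """Fit the full (lambda, rho) grid with warm starts across lambda
    within each rho sweep; each sweep restarts from the null-covariate
    solution.  Points are returned in (rho-major, decreasing-lambda) order.
    """
    if null_state is None:
        null_state = fit_null_state(data, basis, null_fit)
    if penalty_config is None:
        penalty_config = default_penalty_config(data, basis, null_state)
    points: list[PathPoint] = []
    for rho in penalty_config.rho_grid:
        state = null_state.copy()
        for lam in penalty_config.lambda_grid:
            pt = fit_path_point(data, basis, state, lam, rho, **point_kwargs)
            points.append(pt)
            state = pt.state
    return points


# ----------------------------------------------------------------------
# KKT certification
# ----------------------------------------------------------------------
def kkt_residuals(
    state: CoefficientState,
    data: PathData,
    basis: SpectralBasis,
    lam: float,
    rho: float,
) -> dict[str, float]:
    """Worst-case violations of the sparse-group-lasso subgradient
    conditions at ``state`` (exact gradients, not the quadratic model).

    Returns the maximum violation for the unpenalized block, the active
    groups, the inactive groups and the random-effect stationarity.
    """
    family = data.family
    mu = family.inverse_link(state.eta)
    r = (data.y - mu) * data.a / family.phi
    gB = -(data.G_std.T @ r)
    gG = -(data.C.T @ r) if data.interactions else np.zeros(data.p)
    g0 = -(data.X0.T @ r)
    U = data.U_rows(basis)
    gdelta = -(U.T @ r) + state.delta / basis.Lambda

    viol_active = 0.0
    viol_inactive = 0.0
    for j in range(data.p):
        bj, gj = state.beta[j], state.gamma[j] if data.interactions else 0.0
        norm = np.hypot(bj, gj)
        if norm == 0.0:
            sg = max(abs(gG[j]) - rho * lam, 0.0)
            viol_inactive = max(
                viol_inactive, np.hypot(gB[j], sg) - (1 - rho) * lam
            )
        else:
            viol_active = max(
                viol_active, abs(gB[j] + (1 - rho) * lam * bj / norm)
            )
            if gj != 0.0:
                viol_active = max(
                    viol_active,
                    abs(gG[j] + (1 - rho) * lam * gj / norm + rho * lam * np.sign(gj)),
                )
            else:
                viol_active = max(
                    viol_active, abs(gG[j] + 0.0) - rho * lam
                )
    return {
        "unpenalized": float(np.max(np.abs(g0))) if g0.size else 0.0,
        "active": float(viol_active),
        "inactive": float(max(viol_inactive, 0.0)),
        "random_effects": float(np.max(np.abs(gdelta))),
    }
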