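"""Path algorithm: prox operator, objective, random-effect updates,
lambda-max and the solution path invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

import gxemix as gx
from gxemix.families import binomial, gaussian
from gxemix.kinship import spectral_decompose
from gxemix.null_model import NullFit
from gxemix.penalized_path import (
    CoefficientState,
    PathData,
    PenaltyConfig,
    compute_lambda_max,
    default_penalty_config,
    fit_null_state,
    fit_path_point,
    objective_value,
    penalty_value,
    prox_sparse_group,
    solution_path,
    update_random_effects,
)


def _numeric_prox(u, t, lam, rho):
    """Independent oracle: numeric minimizer of
    0.5||x-u||^2 + t[(1-rho)lam||x|| + rho lam |x2|]."""
    def f(x):
        return 0.5 * np.sum((x - u) ** 2) + t * (
            (1 - rho) * lam * np.hypot(*x) + rho * lam * abs(x[1])
        )
    best = None
    for x0 in ([0.0, 0.0], list(u), [u[0], 0.0]):
        r = minimize(f, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    return best.x


class TestProx:
    def test_identity_at_zero_penalty(self):
        assert prox_sparse_group(1.3, -0.4, 0.5, 0.0, 0.3) == (1.3, -0.4)

    def test_zero_maps_to_zero(self):
        assert prox_sparse_group(0.0, 0.0, 1.0, 2.0, 0.5) == (0.0, 0.0)

    def test_hand_computed_value(self):
        b, g = prox_sparse_group(1.0, 1.0, 1.0, 1.0, 0.5)
        assert b == pytest.approx(0.55279, abs=1e-5)
        assert g == pytest.approx(0.27639, abs=1e-5)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            prox_sparse_group(1.0, 1.0, 0.0, 1.0, 0.5)

    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            u = rng.normal(scale=2.0, size=2)
            t = rng.uniform(0.1, 2.0)
            lam = rng.uniform(0.0, 2.0)
            rho = rng.uniform(0.0, 0.95)
            ours = np.array(prox_sparse_group(u[0], u[1], t, lam, rho))
            ref = _numeric_prox(u, t, lam, rho)
            np.testing.assert_allclose(ours, ref, atol=1e-5)

    def test_strong_hierarchy(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            u = rng.normal(scale=2.0, size=2)
            b, g = prox_sparse_group(
                u[0], u[1], rng.uniform(0.1, 2), rng.uniform(0, 2),
                rng.uniform(0, 0.95),
            )
            if g != 0.0 and u[0] != 0.0:
                assert b != 0.0


def _tiny_problem(seed=0, n=40, p=6, interactions=True):
    ds = gx.simulate_dataset(n=n, p=p, n_causal_main=3, n_causal_gei=2,
                             n_kinship_snps=100, seed=seed)
    Z = np.column_stack([np.ones(n), ds.age])
    null = gx.fit_null_pql_aireml(ds.y, Z, ds.sex, ds.kin.K, ds.kin.K_D)
    basis = spectral_decompose(max(null.tau_g, 1e-8), null.tau_d,
                               ds.kin.K, ds.kin.K_D)
    data = PathData(y=ds.y, Z=Z, D=ds.sex, G_std=ds.G_std,
                    interactions=interactions)
    return ds, data, null, basis


class TestObjective:
    def test_zero_support_contributes_no_penalty(self):
        assert penalty_value(np.zeros(5), np.zeros(5), 3.0, 0.4) == 0.0

    def test_lambda_zero_is_pure_fit_term(self):
        _, data, null, basis = _tiny_problem()
        st = fit_null_state(data, basis, null)
        q0 = objective_value(st, data, basis.Lambda, 0.0, 0.0)
        q1 = objective_value(st, data, basis.Lambda, 5.0, 0.5)
        assert q0 == q1  # support empty, so penalty adds nothing either way

    def test_single_bernoulli_log2(self):
        data = PathData(
            y=np.array([1.0]), Z=np.ones((1, 1)), D=None,
            G_std=np.zeros((1, 1)), interactions=False,
        )
        st = CoefficientState(
            coef0=np.zeros(1), beta=np.zeros(1), gamma=np.zeros(1),
            delta=np.zeros(1), eta=np.zeros(1),
        )
        basis = spectral_decompose(1.0, 0.0, np.eye(1))
        assert objective_value(st, data, basis.Lambda, 0.0, 0.0) == (
            pytest.approx(np.log(2))
        )


class TestRandomEffectUpdate:
    def test_infinite_ridge_shrinks_to_zero(self):
        _, data, null, basis = _tiny_problem()
        st = fit_null_state(data, basis, null)
        tiny = type(basis)(U=basis.U, Lambda=np.full(basis.n, 1e-12),
                           tau=basis.tau)
        delta = update_random_effects(st, data, tiny)
        assert np.max(np.abs(delta)) < 1e-6

    def test_scalar_gaussian_ridge(self):
        """n=1 identity-link ridge: minimize (1-d)^2/2 + d^2/2 -> d = 1/2."""
        data = PathData(
            y=np.array([1.0]), Z=np.ones((1, 1)), D=None,
            G_std=np.zeros((1, 1)), family=gaussian(estimate_phi=False),
            interactions=False,
        )
        st = CoefficientState(
            coef0=np.zeros(1), beta=np.zeros(1), gamma=np.zeros(1),
            delta=np.zeros(1), eta=np.zeros(1),
        )
        basis = spectral_decompose(1.0, 0.0, np.eye(1))
        delta = update_random_effects(st, data, basis)
        assert delta[0] == pytest.approx(0.5)

    def test_descent_of_fit_term(self):
        _, data, null, basis = _tiny_problem(seed=3)
        st = fit_null_state(data, basis, null)
        st.delta = np.zeros(basis.n)
        st.eta = data.X0 @ st.coef0

        def f(state):
            return objective_value(state, data, basis.Lambda, 0.0, 0.0)

        before = f(st)
        st.delta = update_random_effects(st, data, basis)
        st.eta = data.X0 @ st.coef0 + data.U_rows(basis) @ st.delta
        assert f(st) <= before + 1e-10


class TestLambdaMax:
    def test_rho_zero_closed_form(self):
        _, data, null, basis = _tiny_problem(seed=1)
        st = fit_null_state(data, basis, null)
        lam = compute_lambda_max(st, data, 0.0, basis)
        mu = data.family.inverse_link(st.eta)
        r = data.y - mu
        expected = np.max(np.hypot(data.G_std.T @ r, data.C.T @ r))
        assert lam == pytest.approx(expected, rel=1e-10)

    def test_single_group_direct_value(self):
        # one group with gradient (3, 0) at rho=0 -> lambda_max = 3
        data = PathData(
            y=np.array([1.0, 0.0]), Z=np.ones((2, 1)), D=None,
            G_std=np.array([[3.0], [3.0]]), interactions=False,
        )
        basis = spectral_decompose(1e-8, 0.0, np.eye(2))
        st = CoefficientState(
            coef0=np.zeros(1), beta=np.zeros(1), gamma=np.zeros(1),
            delta=np.zeros(2), eta=np.zeros(2),
        )
        st.eta = np.zeros(2)
        mu = data.family.inverse_link(st.eta)
        grad = abs(float(data.G_std[:, 0] @ (data.y - mu)))
        lam = compute_lambda_max(st, data, 0.0, basis)
        assert lam == pytest.approx(grad)

    def test_zero_support_at_lambda_max_all_rho(self):
        _, data, null, basis = _tiny_problem(seed=2)
        ns = fit_null_state(data, basis, null)
        for rho in np.linspace(0.0, 0.9, 10):
            lam = compute_lambda_max(ns, data, rho, basis)
            pt = fit_path_point(data, basis, ns.copy(), lam, rho)
            assert pt.size_main == 0 and pt.size_gei == 0


class TestPathPoint:
    def test_monotone_outer_descent(self):
        _, data, null, basis = _tiny_problem(seed=4)
        ns = fit_null_state(data, basis, null)
        lam = 0.3 * compute_lambda_max(ns, data, 0.5, basis)
        objs = []
        st = ns.copy()
        for _ in range(8):
            pt = fit_path_point(data, basis, st, lam, 0.5, max_outer=1,
                                tol_outer=0.0)
            st = pt.state
            objs.append(pt.objective)
        assert np.all(np.diff(objs) <= 1e-8)

    def test_single_coefficient_matches_scalar_oracle(self):
        """One beta-only group at rho=0: the fitted coefficient matches a
        brute-force scalar minimizer of the penalized quasi-likelihood."""
        rng = np.random.default_rng(8)
        n = 120
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.9 * x)))).astype(float)
        data = PathData(y=y, Z=np.ones((n, 1)), D=None,
                        G_std=x[:, None], interactions=False)
        basis = spectral_decompose(1e-8, 0.0, np.eye(n))
        null = NullFit(theta=np.zeros(1), alpha=0.0, tau_g=1e-8, tau_d=0.0,
                       phi=1.0, b=np.zeros(n), converged=True, n_iter=0)
        ns = fit_null_state(data, basis, null)
        lam = 8.0
        pt = fit_path_point(data, basis, ns.copy(), lam, 0.0,
                            tol_inner=1e-10, tol_outer=1e-12, max_outer=200)

        def pen_nll(params):
            a, b = params
            eta = a + b * x
            return float(
                np.sum(np.logaddexp(0.0, eta) - y * eta) + lam * abs(b)
            )

        from scipy.optimize import minimize
        ref = minimize(pen_nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        assert pt.state.beta[0] == pytest.approx(ref.x[1], abs=1e-6)

    def test_hierarchy_and_support_growth_along_path(self):
        _, data, null, basis = _tiny_problem(seed=5, n=80, p=12)
        ns = fit_null_state(data, basis, null)
        pen = default_penalty_config(data, basis, ns, n_lambda=12, n_rho=4)
        pts = solution_path(data, null, basis, pen, null_state=ns)
        assert len(pts) == 48
        for pt in pts:
            gam_nz = pt.state.gamma != 0
            assert np.all(pt.state.beta[gam_nz] != 0)
        for r in range(4):
            sweep = pts[r * 12:(r + 1) * 12]
            assert sweep[0].size_main == 0
            assert sweep[-1].size_main >= sweep[0].size_main

    def test_default_grid_has_500_points(self):
        cfg = PenaltyConfig.default(lambda_max=2.0)
        assert cfg.lambda_grid.size * cfg.rho_grid.size == 500
        assert cfg.lambda_grid[-1] == pytest.approx(0.02)
        assert np.all(np.diff(cfg.lambda_grid) < 0)
        np.testing.assert_allclose(cfg.rho_grid, np.linspace(0, 0.9, 10))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            PenaltyConfig(np.array([1.0, 2.0]), np.array([0.0]), 2.0)
        with pytest.raises(ValueError):
            PenaltyConfig(np.array([2.0, 1.0]), np.array([1.0]), 2.0)
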