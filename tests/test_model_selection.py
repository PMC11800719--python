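"""Cross-validation, AUC and out-of-sample prediction."""

import numpy as np
import pytest

import gxemix as gx
from gxemix.model_selection import (
    auc,
    cross_validate,
    predict_probabilities,
    stratified_folds,
    _deviance,
)
from gxemix.null_model import NullFit
from gxemix.penalized_path import (
    CoefficientState,
    default_penalty_config,
    fit_null_state,
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert auc([0.9, 0.4, 0.6], [1, 1, 0]) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=50)
        y = rng.binomial(1, 0.5, 50)
        assert auc(s, y) == pytest.approx(auc(np.exp(2 * s) + 3, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestFolds:
    def test_partition_and_reproducibility(self):
        y = np.r_[np.zeros(30), np.ones(20)]
        f1 = stratified_folds(y, 5, seed=3)
        f2 = stratified_folds(y, 5, seed=3)
        np.testing.assert_array_equal(f1, f2)
        assert set(f1) == set(range(5))
        # stratification: each fold keeps both classes
        for k in range(5):
            assert len(np.unique(y[f1 == k])) == 2

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([0, 1]), 1, 0)


@pytest.fixture(scope="module")
def cv_problem():
    ds = gx.simulate_dataset(n=150, p=30, n_causal_main=5, n_causal_gei=3,
                             n_kinship_snps=300, seed=21)
    Z = np.column_stack([np.ones(150), ds.age])
    null = gx.fit_null_pql_aireml(ds.y, Z, ds.sex, ds.kin.K, ds.kin.K_D)
    basis = gx.spectral_decompose(max(null.tau_g, 1e-8), null.tau_d,
                                  ds.kin.K, ds.kin.K_D)
    data = gx.PathData(y=ds.y, Z=Z, D=ds.sex, G_std=ds.G_std)
    ns = fit_null_state(data, basis, null)
    pen = default_penalty_config(data, basis, ns, n_lambda=8, n_rho=3)
    return ds, data, null, basis, pen


class TestCrossValidate:
    def test_surface_shape_and_choice_is_optimum(self, cv_problem):
        _, data, null, basis, pen = cv_problem
        res = cross_validate(data, null, basis, pen, folds=4, seed=1)
        assert res.mean_metric.shape == (8, 3)
        li, ri = res.best_index
        assert res.mean_metric[li, ri] == pytest.approx(res.mean_metric.min())
        assert res.best_lambda == pen.lambda_grid[li]
        # fold labels partition the samples
        assert set(res.fold_assignments) == set(range(4))

    def test_reproducible_under_seed(self, cv_problem):
        _, data, null, basis, pen = cv_problem
        r1 = cross_validate(data, null, basis, pen, folds=3, seed=7)
        r2 = cross_validate(data, null, basis, pen, folds=3, seed=7)
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)
        np.testing.assert_allclose(r1.mean_metric, r2.mean_metric)
        assert (r1.best_lambda, r1.best_rho) == (r2.best_lambda, r2.best_rho)

    def test_lambda_max_point_equals_null_deviance(self, cv_problem):
        """When validation data duplicates the training data, the deviance
        of the lambda_max model (zero penalized support) reduces to the
        covariate-only mixed-model deviance."""
        from gxemix.penalized_path import fit_path_point

        _, data, null, basis, pen = cv_problem
        ns = fit_null_state(data, basis, null)
        eta0 = data.X0 @ ns.coef0 + data.U_rows(basis) @ ns.delta
        null_dev = float(np.mean(_deviance(
            data.y, data.family.inverse_link(eta0)
        )))
        pt = fit_path_point(data, basis, ns.copy(), pen.lambda_max, 0.0)
        dev = float(np.mean(_deviance(
            data.y, data.family.inverse_link(pt.state.eta)
        )))
        assert pt.size_main == 0 and pt.size_gei == 0
        assert dev == pytest.approx(null_dev, abs=1e-6)

    def test_bad_metric_rejected(self, cv_problem):
        _, data, null, basis, pen = cv_problem
        with pytest.raises(ValueError):
            cross_validate(data, null, basis, pen, metric="accuracy")


class TestPredict:
    def _state(self, p, coef0=None, beta=None, gamma=None):
        return CoefficientState(
            coef0=np.zeros(2) if coef0 is None else np.asarray(coef0, float),
            beta=np.zeros(p) if beta is None else np.asarray(beta, float),
            gamma=np.zeros(p) if gamma is None else np.asarray(gamma, float),
            delta=np.zeros(1), eta=np.zeros(1),
        )

    def _null(self, tau_g=1.0, b=None):
        b = np.zeros(1) if b is None else np.asarray(b, float)
        return NullFit(theta=np.zeros(1), alpha=0.0, tau_g=tau_g, tau_d=0.0,
                       phi=1.0, b=b, converged=True, n_iter=1)

    def test_empty_model_gives_half(self):
        prob = predict_probabilities(
            self._state(3), self._null(), np.ones((4, 1)), np.zeros(4),
            np.zeros((4, 3)),
        )
        np.testing.assert_allclose(prob, 0.5)

    def test_zero_cross_kinship_matches_fixed_only(self):
        st = self._state(2, coef0=[0.3, -0.2], beta=[0.5, 0.0])
        G = np.array([[1.0, 0.0], [-1.0, 2.0]])
        base = predict_probabilities(
            st, self._null(), np.ones((2, 1)), np.ones(2), G,
        )
        with_zero = predict_probabilities(
            st, self._null(b=[0.8]), np.ones((2, 1)), np.ones(2), G,
            K_cross=np.zeros((2, 1)), K_train=np.array([[1.0]]),
            K_D_cross=np.zeros((2, 1)), K_D_train=np.array([[1.0]]),
        )
        np.testing.assert_allclose(base, with_zero)

    def test_conditional_mean_transfer(self):
        """1 train subject, tau_g=1, K=[[1]], K_cross=[[0.5]], b=0.8 ->
        transferred random effect 0.4."""
        st = self._state(1)
        prob = predict_probabilities(
            st, self._null(tau_g=1.0, b=[0.8]), np.ones((1, 1)),
            np.zeros(1), np.zeros((1, 1)),
            K_cross=np.array([[0.5]]), K_train=np.array([[1.0]]),
        )
        expected = 1 / (1 + np.exp(-0.4))
        assert prob[0] == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            predict_probabilities(
                self._state(3), self._null(), np.ones((2, 1)), None,
                np.zeros((2, 5)),
            )

    def test_empty_support_depends_only_on_unpenalized(self):
        st = self._state(4, coef0=[0.7, 0.1])
        g1 = np.zeros((3, 4))
        rng = np.random.default_rng(5)
        g2 = rng.normal(size=(3, 4))
        p1 = predict_probabilities(st, self._null(), np.ones((3, 1)),
                                   np.ones(3), g1)
        p2 = predict_probabilities(st, self._null(), np.ones((3, 1)),
                                   np.ones(3), g2)
        np.testing.assert_allclose(p1, p2)
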