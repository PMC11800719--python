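"""Synthetic-cohort generator: structure, effect draws, random effects and
the phenotype model."""

import numpy as np
import pytest

import gxemix as gx
from gxemix.kinship import compute_grm, standardize_genotypes
from gxemix.simulate import (
    SimulationConfig,
    draw_effects,
    simulate_phenotypes,
    simulate_random_effect,
    simulate_structured_genotypes,
)


class TestStructuredGenotypes:
    def test_determinism(self):
        p1, l1 = simulate_structured_genotypes(80, 50, seed=5)
        p2, l2 = simulate_structured_genotypes(80, 50, seed=5)
        np.testing.assert_array_equal(p1.G, p2.G)
        np.testing.assert_array_equal(l1, l2)

    def test_two_populations_separate_on_leading_pc(self):
        rs = []
        for seed in range(10):
            panel, labels = simulate_structured_genotypes(
                500, 2000, n_pops=2, F=0.2, seed=seed
            )
            K = compute_grm(standardize_genotypes(panel))
            _, vecs = np.linalg.eigh(K)
            pc1 = vecs[:, -1]
            r = np.corrcoef(pc1, labels)[0, 1]
            rs.append(abs(r))
        assert np.mean(rs) > 0.9

    def test_vanishing_drift_collapses_structure(self):
        gaps = {}
        for F in (1e-4, 0.2):
            panel, _ = simulate_structured_genotypes(
                300, 1500, n_pops=2, F=F, seed=1
            )
            lam = np.linalg.eigvalsh(compute_grm(standardize_genotypes(panel)))
            gaps[F] = lam[-1] - lam[-2]
        assert gaps[1e-4] < 0.1 * gaps[0.2]

    def test_bad_drift_rejected(self):
        with pytest.raises(ValueError):
            simulate_structured_genotypes(10, 5, F=0.0)


class TestEffects:
    def test_hierarchical_total_causal(self):
        cfg = SimulationConfig(n=100, p=500, seed=0, hierarchy=True,
                               n_causal_main=100, n_causal_gei=50)
        beta, gamma, S, Sp = draw_effects(cfg, np.random.default_rng(0))
        assert set(Sp) <= set(S)
        assert len(set(S) | set(Sp)) == 100
        assert np.count_nonzero(beta) == 100
        assert np.count_nonzero(gamma) == 50

    def test_non_hierarchical_total_causal(self):
        cfg = SimulationConfig(n=100, p=500, seed=0, hierarchy=False,
                               n_causal_main=100, n_causal_gei=50)
        _, _, S, Sp = draw_effects(cfg, np.random.default_rng(1))
        assert len(set(S) & set(Sp)) == 0
        assert len(set(S) | set(Sp)) == 150

    def test_effect_size_variance(self):
        """Main-effect draws have the stated variance h2_s*sigma2/|S|
        (= 0.018 at the low-polygenic defaults)."""
        cfg = SimulationConfig(n=10, p=200_000, n_causal_main=100_000,
                               n_causal_gei=50, seed=0)
        beta, _, S, _ = draw_effects(cfg, np.random.default_rng(2))
        v = beta[S].var()
        target = 0.2 * 9.0 / cfg.n_causal_main  # h2_s * sigma2 / |S|
        mc_se = target * np.sqrt(2 / cfg.n_causal_main)
        assert abs(v - target) < 3 * mc_se

    def test_hierarchy_flag_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n=10, p=100, n_causal_main=5, n_causal_gei=10,
                             hierarchy=True)


class TestRandomEffect:
    def test_zero_fractions_give_zero(self):
        eps = simulate_random_effect(np.eye(5), None, 0.0, 0.0, 9.0, seed=0)
        np.testing.assert_array_equal(eps, np.zeros(5))

    def test_identity_covariance_variance(self):
        rng = np.random.default_rng(3)
        draws = np.stack([
            simulate_random_effect(np.eye(50), None, 1.0 / 9.0, 0.0, 9.0, rng)
            for _ in range(2000)
        ])
        v = draws.var(axis=0).mean()
        assert v == pytest.approx(1.0, abs=3 * np.sqrt(2 / 2000))

    def test_covariance_recovery(self):
        rng = np.random.default_rng(4)
        n = 20
        A = rng.normal(size=(n, 30))
        K = A @ A.T / 30 + 0.3 * np.eye(n)
        D = rng.binomial(1, 0.5, n).astype(float)
        K_D = gx.build_gxe_kinship(K, D, "binary")
        h2g, h2d, s2 = 0.2, 0.1, 9.0
        draws = np.stack([
            simulate_random_effect(K, K_D, h2g, h2d, s2, rng)
            for _ in range(5000)
        ])
        emp = np.cov(draws.T)
        target = h2g * s2 * K + h2d * s2 * K_D
        # entrywise MC standard error of a covariance estimate
        se = np.sqrt(
            (np.outer(np.diag(target), np.diag(target)) + target**2) / 5000
        )
        assert np.max(np.abs(emp - target) / se) < 5


class TestPhenotypes:
    def test_null_configuration_is_fair_coin(self):
        n = 2000
        rng = np.random.default_rng(5)
        G = np.zeros((n, 3))
        y = simulate_phenotypes(
            G, np.zeros(n, dtype=int), np.array([0.5]), np.zeros(n),
            np.zeros(n), np.zeros(3), np.zeros(3), np.zeros(n), rng,
        )
        assert y.mean() == pytest.approx(0.5, abs=0.05)

    def test_sex_and_age_coefficients(self):
        """The generative model uses -log(1.3) per exposure unit and
        log(1.05) per decade of age."""
        rng = np.random.default_rng(6)
        n = 200_000
        sex = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        y = simulate_phenotypes(
            np.zeros((n, 1)), np.zeros(n, dtype=int), np.array([0.5]),
            np.zeros(n), sex, np.zeros(1), np.zeros(1), np.zeros(n), rng,
        )
        p0, p1 = y[: n // 2].mean(), y[n // 2:].mean()
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(1 / 1.3, rel=0.05)

    def test_missing_population_rejected(self):
        with pytest.raises(ValueError, match="population"):
            simulate_phenotypes(
                np.zeros((2, 1)), np.array([0, 3]), np.array([0.5]),
                np.zeros(2), np.zeros(2), np.zeros(1), np.zeros(1),
                np.zeros(2), np.random.default_rng(0),
            )


class TestFullDataset:
    def test_determinism_and_invariants(self):
        ds1 = gx.simulate_dataset(n=120, p=80, n_causal_main=10,
                                  n_causal_gei=5, n_kinship_snps=200, seed=9)
        ds2 = gx.simulate_dataset(n=120, p=80, n_causal_main=10,
                                  n_causal_gei=5, n_kinship_snps=200, seed=9)
        np.testing.assert_array_equal(ds1.panel.G, ds2.panel.G)
        np.testing.assert_array_equal(ds1.y, ds2.y)
        np.testing.assert_array_equal(ds1.beta, ds2.beta)
        # hierarchy: gamma support within beta support
        assert set(np.flatnonzero(ds1.gamma)) <= set(np.flatnonzero(ds1.beta))
        assert set(ds1.y) <= {0.0, 1.0}
        # kinship built from a disjoint SNP set: K is not a function of the
        # candidate panel (perturbing candidates leaves K unchanged)
        assert ds1.kin.K.shape == (120, 120)

    def test_variance_budget(self):
        """Empirical logit-scale variance fractions of the four genetic
        components track (h2_s, h2_sp, h2_g, h2_d)."""
        fracs = []
        for seed in range(5):
            ds = gx.simulate_dataset(
                n=400, p=600, n_causal_main=100, n_causal_gei=50,
                n_kinship_snps=600, seed=seed,
            )
            s2 = ds.config.sigma2
            main = ds.G_std @ ds.beta
            gei = (ds.sex[:, None] * ds.G_std) @ ds.gamma
            fracs.append(
                (main.var() / s2, gei.var() / s2, ds.random_effect.var() / s2)
            )
        mean = np.array(fracs).mean(axis=0)
        assert mean[0] == pytest.approx(0.2, rel=0.25)
        # GEI columns are active for the exposed half only: expected
        # empirical variance is h2_sp * (var share among exposed ~ 1/2 +
        # quarter from the exposure indicator mean); allow a loose band
        assert 0.03 < mean[1] < 0.12
        # diag(K_D) = diag(K), so the random-effect variance per subject is
        # about (h2_g + h2_d) * mean(diag K)
        assert mean[2] == pytest.approx(
            ds.config.h2_g + ds.config.h2_d, rel=0.6
        )
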