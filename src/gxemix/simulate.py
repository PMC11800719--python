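"""Synthetic data generator for the simulation design.

Emulates a structured multi-population cohort: genotypes are drawn from the
Balding-Nichols model (seven populations, sample shares matching the
HGDP+1000G composition, drift parameter F), a binary exposure plays the
role of sex, and binary phenotypes follow the logistic mixed model

    logit(pi_i) = logit(pi0_k) - log(1.3) * Sex_i + log(1.05) * Age_i / 10
                  + sum_{j in S} beta_j Gs_ij
                  + sum_{j in S'} gamma_j (Sex_i * Gs_ij) + eps_i

with population-specific baseline prevalences ``pi0_k ~ U(0.1, 0.9)``,
standardized genotypes ``Gs``, causal main-effect set S (|S| = 100 by
default, beta_j ~ N(0, h2_S sigma2 / |S|)), causal GEI set S'
(|S'| = 50, gamma_j ~ N(0, h2_S' sigma2 / |S'|)) and a two-component
polygenic random effect ``eps ~ N(0, h2_g sigma2 K + h2_d sigma2 K_D)``.
The kinship matrices are built from a SNP panel disjoint from the
candidates.

Defaults reproduce the low-polygenic study condition
(h2_S, h2_S', h2_g, h2_d, sigma2) = (0.2, 0.1, 0.2, 0.1, 9); the
high-polygenic condition uses (0.4, 0.2) with sigma2 = 35.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinship as ks
from .kinship import GenotypePanel, KinshipPair

__all__ = [
    "POPULATION_SHARES",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_structured_genotypes",
    "draw_effects",
    "simulate_random_effect",
    "simulate_phenotypes",
    "simulate_dataset",
]

# Sample shares of the seven continental populations in the reference panel
POPULATION_SHARES: dict[str, float] = {
    "African": 0.24,
    "AdmixedAmerican": 0.13,
    "CentralSouthAsian": 0.19,
    "EastAsian": 0.20,
    "European": 0.19,
    "MiddleEastern": 0.04,
    "Oceanian": 0.01,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    ``h2_s``/``h2_sp`` are the logit-scale variance fractions of the causal
    main and GEI fixed effects; ``h2_g``/``h2_d`` those of the polygenic and
    polygenic-by-exposure random effects; ``sigma2`` the total logit-scale
    variance these fractions refer to.  ``hierarchy=True`` draws the GEI
    causal set as a subset of the main causal set (100 causal SNPs in
    total); ``False`` draws it disjointly (150 causal SNPs).
    """

    n: int = 4097
    p: int = 10_000
    n_causal_main: int = 100
    n_causal_gei: int = 50
    h2_s: float = 0.2
    h2_sp: float = 0.1
    h2_g: float = 0.2
    h2_d: float = 0.1
    sigma2: float = 9.0
    hierarchy: bool = True
    n_populations: int = 7
    F: float = 0.1
    n_kinship_snps: int = 5_000
    maf_min: float = 0.01
    exposure_by_population: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.F <= 0.5):
            raise ValueError("drift parameter F must lie in (0, 0.5]")
        if self.h2_s + self.h2_sp + self.h2_g + self.h2_d >= 1.0:
            raise ValueError("variance fractions must sum to < 1")
        if self.hierarchy and self.n_causal_gei > self.n_causal_main:
            raise ValueError("hierarchy requires |S'| <= |S|")
        if self.n_causal_main > self.p or self.n_causal_gei > self.p:
            raise ValueError("causal sets cannot exceed p")


@dataclass
class SimulatedDataset:
    """A complete simulated cohort with its generating truth."""

    panel: GenotypePanel
    G_std: np.ndarray
    populations: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    causal_main: np.ndarray
    causal_gei: np.ndarray
    random_effect: np.ndarray
    y: np.ndarray
    kin: KinshipPair
    pi0: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def exposure(self) -> np.ndarray:
        return self.sex


def _population_sizes(n: int, n_pops: int) -> np.ndarray:
    shares = np.array(list(POPULATION_SHARES.values())[:n_pops], dtype=float)
    shares = shares / shares.sum()
    sizes = np.floor(shares * n).astype(int)
    sizes[0] += n - sizes.sum()  # assign the rounding remainder
    return sizes


def simulate_structured_genotypes(
    n: int,
    p: int,
    n_pops: int = 7,
    F: float = 0.1,
    seed: int | np.random.Generator = 0,
    maf_min: float = 0.01,
    max_redraws: int = 50,
) -> tuple[GenotypePanel, np.ndarray]:
    """Balding-Nichols structured genotypes.

    Ancestral frequencies ``q_j ~ U(0.05, 0.5)``; population-specific
    frequencies ``~ Beta(q (1-F)/F, (1-q)(1-F)/F)``; genotypes
    ``Binomial(2, freq)``.  Population sizes follow the reference-panel
    shares.  Columns that come out monomorphic or below ``maf_min`` in the
    realized sample are redrawn so the panel standardizes cleanly.
    """
    if not (0 < F <= 0.5):
        raise ValueError("drift parameter F must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = _population_sizes(n, n_pops)
    labels = np.repeat(np.arange(n_pops), sizes)

    G = np.empty((n, p), dtype=np.int8)
    cols = np.arange(p)
    for _ in range(max_redraws):
        q = rng.uniform(0.05, 0.5, size=cols.size)
        shape = (1.0 - F) / F
        start = 0
        for k, nk in enumerate(sizes):
            fk = rng.beta(q * shape, (1.0 - q) * shape)
            fk = np.clip(fk, 1e-6, 1 - 1e-6)
            G[start:start + nk, cols] = rng.binomial(
                2, fk, size=(nk, cols.size)
            ).astype(np.int8)
            start += nk
        freq = G[:, cols].mean(axis=0) / 2.0
        bad = np.minimum(freq, 1 - freq) < maf_min
        if not np.any(bad):
            break
        cols = cols[bad]
    else:
        raise RuntimeError("could not draw polymorphic SNPs; increase n or F")
    panel = GenotypePanel(G.astype(float))
    return panel, labels


def draw_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw causal sets and effect sizes.

    beta_j ~ N(0, h2_s sigma2 / |S|) on S; gamma_j ~ N(0, h2_sp sigma2 /
    |S'|) on S'.  Under hierarchy S' is a subset of S; otherwise S' is
    drawn disjointly from S.
    """
    p = config.p
    perm = rng.permutation(p)
    S = np.sort(perm[: config.n_causal_main])
    if config.hierarchy:
        S_prime = np.sort(rng.choice(S, size=config.n_causal_gei, replace=False))
    else:
        S_prime = np.sort(
            perm[config.n_causal_main:config.n_causal_main + config.n_causal_gei]
        )
    beta = np.zeros(p)
    gamma = np.zeros(p)
    beta[S] = rng.normal(
        0.0, np.sqrt(config.h2_s * config.sigma2 / config.n_causal_main),
        size=config.n_causal_main,
    )
    gamma[S_prime] = rng.normal(
        0.0, np.sqrt(config.h2_sp * config.sigma2 / config.n_causal_gei),
        size=config.n_causal_gei,
    )
    return beta, gamma, S, S_prime


def simulate_random_effect(
    K: np.ndarray,
    K_D: np.ndarray | None,
    h2_g: float,
    h2_d: float,
    sigma2: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One draw ``eps ~ N(0, h2_g sigma2 K + h2_d sigma2 K_D)``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = np.asarray(K).shape[0]
    cov = h2_g * sigma2 * np.asarray(K, dtype=float)
    if h2_d != 0.0:
        if K_D is None:
            raise ValueError("h2_d > 0 requires K_D")
        cov = cov + h2_d * sigma2 * np.asarray(K_D, dtype=float)
    if not np.any(cov):
        return np.zeros(n)
    lam, V = np.linalg.eigh((cov + cov.T) / 2.0)
    if lam[0] < -1e-8 * max(1.0, lam[-1]):
        raise ValueError("random-effect covariance is not PSD")
    lam = np.clip(lam, 0.0, None)
    return V @ (np.sqrt(lam) * rng.standard_normal(n))


def simulate_phenotypes(
    G_std: np.ndarray,
    populations: np.ndarray,
    pi0: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    random_effect: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli phenotypes from the generating logistic model."""
    populations = np.asarray(populations)
    if np.any(populations < 0) or np.any(populations >= pi0.shape[0]):
        raise ValueError("missing population label / prevalence")
    eta = (
        np.log(pi0 / (1.0 - pi0))[populations]
        - np.log(1.3) * sex
        + np.log(1.05) * age / 10.0
        + G_std @ beta
        + (sex[:, None] * G_std[:, gamma != 0]) @ gamma[gamma != 0]
        + random_effect
    )
    pi = 1.0 / (1.0 + np.exp(-eta))
    return rng.binomial(1, pi).astype(float)


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Generate a full cohort under the given study condition.

    Kinship is built from ``config.n_kinship_snps`` SNPs drawn independently
    of the candidate panel (disjoint by construction), standardized, and
    stabilized to positive definiteness before use.
    """
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)

    panel, labels = simulate_structured_genotypes(
        config.n, config.p, config.n_populations, config.F, rng,
        maf_min=config.maf_min,
    )
    G_std = ks.standardize_genotypes(panel)

    kin_panel, _ = simulate_structured_genotypes(
        config.n, config.n_kinship_snps, config.n_populations, config.F, rng,
        maf_min=config.maf_min,
    )
    K = ks.compute_grm(ks.standardize_genotypes(kin_panel))
    K, _ = ks.ensure_positive_definite(K)

    # exposure: balanced Bernoulli by default; optionally population-tilted
    # to induce gene-environment dependence
    if config.exposure_by_population:
        probs = np.linspace(0.3, 0.7, config.n_populations)
        sex = rng.binomial(1, probs[labels]).astype(float)
    else:
        sex = rng.binomial(1, 0.5, size=config.n).astype(float)
    K_D = ks.build_gxe_kinship(K, sex, kind="binary")

    age = rng.normal(50.0, 10.0, size=config.n)
    beta, gamma, S, S_prime = draw_effects(config, rng)
    eps = simulate_random_effect(
        K, K_D, config.h2_g, config.h2_d, config.sigma2, rng
    )
    pi0 = rng.uniform(0.1, 0.9, size=config.n_populations)
    y = simulate_phenotypes(
        G_std, labels, pi0, age, sex, beta, gamma, eps, rng
    )
    kin = KinshipPair(K=K, K_D=K_D, exposure=sex, exposure_kind="binary")
    return SimulatedDataset(
        panel=panel, G_std=G_std, populations=labels, age=age, sex=sex,
        beta=beta, gamma=gamma, causal_main=S, causal_gei=S_prime,
        random_effect=eps, y=y, kin=kin, pi0=pi0, config=config,
    )
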