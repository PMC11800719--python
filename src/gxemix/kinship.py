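"""Genetic similarity and gene-by-environment kinship matrices.

The polygenic random effect in the mixed model has covariance
``tau_g * K + tau_d * K_D`` where

* ``K`` is the genetic similarity matrix (GSM / GRM) built from genome-wide
  standardized genotypes, ``K = G_std @ G_std.T / p``;
* ``K_D`` is the GxE kinship: ``K`` masked (binary exposure) or down-weighted
  (continuous exposure) by exposure dissimilarity.  It captures polygenic
  gene-by-environment covariance between individuals who are both genetically
  related and share an exposure, guarding against spurious interaction
  selection.

A single spectral decomposition of the combined covariance is performed once
after the variance components have been estimated; the eigenbasis then makes
the random-effect ridge term diagonal inside the path algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "GenotypePanel",
    "KinshipPair",
    "SpectralBasis",
    "standardize_genotypes",
    "compute_grm",
    "build_gxe_kinship",
    "stabilize_psd",
    "ensure_positive_definite",
    "spectral_decompose",
]


@dataclass
class GenotypePanel:
    """Minor-allele count matrix with per-SNP allele frequencies.

    ``G`` is an ``n x p`` float array with entries in {0, 1, 2}; missing
    genotypes are NaN.  ``maf`` holds the per-column allele frequency of the
    counted (A1) allele; if not supplied it is computed from the non-missing
    entries.  Monomorphic SNPs (frequency 0 or 1) are rejected because they
    cannot be standardized.
    """

    G: np.ndarray
    maf: np.ndarray | None = None
    sample_ids: Sequence[str] | None = None
    snp_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D matrix")
        n, p = self.G.shape
        valid = np.isnan(self.G) | np.isin(self.G, (0.0, 1.0, 2.0))
        if not np.all(valid):
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype entry outside {{0,1,2}} at sample {i}, SNP {j}: "
                f"{self.G[i, j]!r}"
            )
        if self.maf is None:
            with np.errstate(invalid="ignore"):
                self.maf = np.nanmean(self.G, axis=0) / 2.0
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (p,):
            raise ValueError("maf length must equal the number of SNPs")
        mono = np.flatnonzero(~((self.maf > 0.0) & (self.maf < 1.0)))
        if mono.size:
            ids = self.snp_ids or [f"snp{j}" for j in range(p)]
            raise ValueError(
                f"monomorphic SNP(s) cannot be standardized: "
                f"{[ids[j] for j in mono[:5]]}"
            )
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists inconsistent with G dimensions")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    def filter_maf(self, min_maf: float = 0.01) -> "GenotypePanel":
        """Drop SNPs whose minor-allele frequency is below ``min_maf``."""
        m = np.minimum(self.maf, 1.0 - self.maf)
        keep = m >= min_maf
        return GenotypePanel(
            self.G[:, keep],
            maf=self.maf[keep],
            sample_ids=self.sample_ids,
            snp_ids=[s for s, k in zip(self.snp_ids, keep) if k],
        )


@dataclass
class KinshipPair:
    """Genetic kinship ``K`` together with its GxE counterpart ``K_D``."""

    K: np.ndarray
    K_D: np.ndarray
    exposure: np.ndarray
    exposure_kind: str = "binary"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.K_D = np.asarray(self.K_D, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or self.K_D.shape != (n, n):
            raise ValueError("K and K_D must be square and same-sized")
        if self.exposure.shape != (n,):
            raise ValueError("exposure length must match K")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        if np.any(np.abs(self.K_D) > np.abs(self.K) + 1e-10):
            raise ValueError("|K_D| must not exceed |K| entrywise")


@dataclass
class SpectralBasis:
    """Eigendecomposition ``U diag(Lambda) U^T = tau_g K + tau_d K_D``.

    Eigenvalues are sorted in decreasing order and strictly positive.
    """

    U: np.ndarray
    Lambda: np.ndarray
    tau: tuple[float, float] = field(default=(1.0, 0.0))

    @property
    def n(self) -> int:
        return self.U.shape[0]

    def covariance(self) -> np.ndarray:
        """Reconstruct tau_g*K + tau_d*K_D."""
        return (self.U * self.Lambda) @ self.U.T


def standardize_genotypes(panel: GenotypePanel) -> np.ndarray:
    """Column-standardize minor-allele counts to zero mean, unit variance
    under Hardy-Weinberg: ``(g - 2 p_j) / sqrt(2 p_j (1 - p_j))``.

    Missing genotypes are imputed to 0 after standardization, i.e. to the
    column mean on the original scale.
    """
    p = panel.maf
    G = panel.G
    denom = np.sqrt(2.0 * p * (1.0 - p))
    out = (G - 2.0 * p) / denom
    np.nan_to_num(out, copy=False, nan=0.0)
    return out


def compute_grm(G_std: np.ndarray) -> np.ndarray:
    """Genetic relationship matrix ``K = G_std @ G_std.T / p`` from a
    standardized genotype matrix (PLINK ``--make-rel`` convention).
    """
    G_std = np.asarray(G_std, dtype=float)
    if G_std.ndim != 2 or G_std.shape[1] == 0:
        raise ValueError("standardized genotype matrix must have p >= 1 SNPs")
    K = G_std @ G_std.T / G_std.shape[1]
    # enforce exact symmetry against BLAS rounding
    K = (K + K.T) / 2.0
    return K


def build_gxe_kinship(
    K: np.ndarray,
    D: np.ndarray,
    kind: str = "binary",
    d: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """GxE kinship matrix.

    Binary exposure: ``K_D[i,j] = K[i,j]`` when ``D_i == D_j``, else 0.
    Continuous exposure: ``K_D[i,j] = K[i,j] * (1 - d(D_i, D_j))`` for a
    dissimilarity ``d`` with range [0, 1]; the default is the
    range-normalized absolute difference.
    """
    K = np.asarray(K, dtype=float)
    D = np.asarray(D, dtype=float)
    n = K.shape[0]
    if D.shape != (n,):
        raise ValueError("exposure length must match K")
    if kind == "binary":
        same = D[:, None] == D[None, :]
        return np.where(same, K, 0.0)
    if kind == "continuous":
        if d is None:
            rng = np.ptp(D)
            if rng == 0:
                dist = np.zeros((n, n))
            else:
                dist = np.abs(D[:, None] - D[None, :]) / rng
        else:
            dist = np.asarray(d(D[:, None], D[None, :]), dtype=float)
        if np.any(dist < -1e-12) or np.any(dist > 1.0 + 1e-12):
            raise ValueError("exposure metric d must map into [0, 1]")
        return K * (1.0 - np.clip(dist, 0.0, 1.0))
    raise ValueError(f"unknown exposure kind: {kind!r}")


def stabilize_psd(K: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Return ``K + eps * I`` (ridge jitter for rank-deficient kinship)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    K = np.asarray(K, dtype=float)
    return K + eps * np.eye(K.shape[0])


def ensure_positive_definite(
    K: np.ndarray, eps: float = 1e-4, threshold: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Apply the jitter only when the smallest eigenvalue of ``K`` is at or
    below ``threshold``.  Returns ``(matrix, was_stabilized)``.
    """
    K = np.asarray(K, dtype=float)
    lam_min = eigh(K, eigvals_only=True, subset_by_index=(0, 0))[0]
    if lam_min <= threshold:
        return stabilize_psd(K, eps), True
    return K, False


def spectral_decompose(
    tau_g: float,
    tau_d: float,
    K: np.ndarray,
    K_D: np.ndarray | None = None,
) -> SpectralBasis:
    """Eigendecomposition of ``tau_g K + tau_d K_D`` with eigenvalues sorted
    in decreasing order.  Raises if the combined matrix is not numerically
    positive definite (stabilize K with a larger jitter in that case).
    """
    if tau_g < 0 or tau_d < 0 or tau_g + tau_d <= 0:
        raise ValueError("need tau_g, tau_d >= 0 with tau_g + tau_d > 0")
    Sigma = tau_g * np.asarray(K, dtype=float)
    if tau_d != 0:
        if K_D is None:
            raise ValueError("tau_d > 0 requires K_D")
        Sigma = Sigma + tau_d * np.asarray(K_D, dtype=float)
    Sigma = (Sigma + Sigma.T) / 2.0
    lam, U = eigh(Sigma)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    if lam[-1] <= 0:
        raise ValueError(
            "combined random-effect covariance is not positive definite; "
            "increase the stabilization eps on K"
        )
    return SpectralBasis(U=U, Lambda=lam, tau=(float(tau_g), float(tau_d)))
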