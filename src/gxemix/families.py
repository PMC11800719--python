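"""Exponential-family specifications for quasi-likelihood working models.

Only canonical links are supported: logit for the binomial family (the
primary use case, binary disease phenotypes) and identity for the gaussian
family (used as an analytically tractable test family).  The dispersion
``phi`` is fixed at 1 for binomial data and estimated by REML for gaussian
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FamilySpec", "binomial", "gaussian"]


@dataclass
class FamilySpec:
    """A one-parameter exponential family with canonical link.

    Parameters
    ----------
    name : {"binomial", "gaussian"}
    phi : float
        Dispersion parameter; fixed at 1 for binomial, estimated for
        gaussian.  Conditional variance is ``phi * nu(mu) / a_i``.
    estimate_phi : bool
        Whether the dispersion is a free parameter of the null model.
    """

    name: str
    phi: float = 1.0
    estimate_phi: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.name not in ("binomial", "gaussian"):
            raise ValueError(f"unsupported family: {self.name!r}")
        if self.phi <= 0:
            raise ValueError("dispersion phi must be positive")
        if self.name == "binomial" and self.estimate_phi:
            raise ValueError("phi is fixed at 1 for the binomial family")

    # -- link and variance functions ------------------------------------
    def link(self, mu: np.ndarray) -> np.ndarray:
        """Canonical link g(mu)."""
        mu = np.asarray(mu, dtype=float)
        if self.name == "binomial":
            return np.log(mu) - np.log1p(-mu)
        return mu

    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        eta = np.asarray(eta, dtype=float)
        if self.name == "binomial":
            # numerically stable expit
            out = np.empty_like(eta)
            pos = eta >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
            e = np.exp(eta[~pos])
            out[~pos] = e / (1.0 + e)
            return out
        return eta

    def dlink(self, mu: np.ndarray) -> np.ndarray:
        """g'(mu), the derivative of the link."""
        mu = np.asarray(mu, dtype=float)
        if self.name == "binomial":
            return 1.0 / (mu * (1.0 - mu))
        return np.ones_like(mu)

    def variance(self, mu: np.ndarray) -> np.ndarray:
        """Variance function nu(mu)."""
        mu = np.asarray(mu, dtype=float)
        if self.name == "binomial":
            return mu * (1.0 - mu)
        return np.ones_like(mu)

    def check_mu(self, mu: np.ndarray) -> None:
        """Reject means on the boundary of the domain (degenerate fit)."""
        mu = np.asarray(mu, dtype=float)
        if self.name == "binomial" and (np.any(mu <= 0.0) or np.any(mu >= 1.0)):
            raise ValueError(
                "fitted probabilities on the boundary of (0, 1); the working "
                "model is degenerate (possible separation)"
            )
        if not np.all(np.isfinite(mu)):
            raise ValueError("non-finite fitted means")

    def neg_quasi_loglik(self, y: np.ndarray, eta: np.ndarray,
                         a: np.ndarray | None = None) -> float:
        """Negative quasi-log-likelihood -sum_i ql_i evaluated at linear
        predictor ``eta`` (canonical link, so ql is available in closed form).
        """
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        a = np.ones_like(y) if a is None else np.asarray(a, dtype=float)
        if self.name == "binomial":
            # ql_i = y*eta - log(1 + exp(eta)), up to a constant in y
            return float(np.sum(a * (np.logaddexp(0.0, eta) - y * eta)))
        return float(np.sum(a * (y - eta) ** 2 / (2.0 * self.phi)))


def binomial() -> FamilySpec:
    """Bernoulli family with logit link; phi fixed at 1."""
    return FamilySpec("binomial", phi=1.0, estimate_phi=False)


def gaussian(phi: float = 1.0, estimate_phi: bool = True) -> FamilySpec:
    """Gaussian family with identity link; phi estimated by default."""
    return FamilySpec("gaussian", phi=phi, estimate_phi=estimate_phi)
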