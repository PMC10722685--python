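"""Risk and inequity-in-risk calculations for subgroup targets.

When a single sample-ATE estimate is reported, its mean squared error for a
particular subgroup's effect depends on how far that subgroup's effect sits
from the representation-weighted average. Averaging that risk over a prior on
the subgroup effects — only the second moment ``M = E[tau tau']`` is needed —
gives the Bayes risk, and the difference in Bayes risk between two subgroups
is the inequity measure computed here. Under an exchangeable prior the
inequity of the shared SATE estimate collapses to ``phi^2 (p_j - p_i)`` where
``phi`` is the standard deviation of pairwise subgroup-effect differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorMoments",
    "ExchangeablePrior",
    "InequityResult",
    "risk_sate",
    "inequity_sate",
    "inequity_exchangeable",
    "inequity_unbiased",
    "popoviciu_phi_bound",
]


@dataclass
class PriorMoments:
    """Second-moment matrix ``M = E[tau tau']`` of the subgroup effects.

    May be built directly or from a covariance/mean decomposition
    ``M = Sigma_tau + mu_tau mu_tau'``.
    """

    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("M must be a square matrix")
        if not np.allclose(self.M, self.M.T, atol=1e-8):
            raise ValueError("M must be symmetric")

    @classmethod
    def from_mean_cov(cls, mu_tau, Sigma_tau) -> "PriorMoments":
        mu = np.asarray(mu_tau, dtype=float)
        Sig = np.asarray(Sigma_tau, dtype=float)
        if np.linalg.eigvalsh((Sig + Sig.T) / 2).min() < -1e-8:
            raise ValueError("Sigma_tau must be positive semidefinite")
        return cls(Sig + np.outer(mu, mu))

    @property
    def n_groups(self) -> int:
        return self.M.shape[0]

    def exchangeable_phi(self, rtol: float = 1e-8) -> float:
        """Return ``phi`` if M is compound symmetric (a*I + b*11'), else raise.

        Compound symmetry is the second-moment signature of an exchangeable
        prior; then ``phi^2 = var(tau_i - tau_j) = 2(M_ii - M_ij)``.
        """
        d = np.diag(self.M)
        off = self.M[~np.eye(self.n_groups, dtype=bool)]
        scale = max(1.0, np.abs(self.M).max())
        if self.n_groups > 1:
            if np.ptp(d) > rtol * scale or (len(off) and np.ptp(off) > rtol * scale):
                raise ValueError("prior moments are not compound symmetric; "
                                 "the exchangeable shortcut does not apply")
        phi_sq = 2 * (d[0] - (off[0] if len(off) else 0.0))
        if phi_sq < -rtol * scale:
            raise ValueError("implied phi^2 is negative; M is not a valid second moment")
        return float(np.sqrt(max(phi_sq, 0.0)))


@dataclass
class ExchangeablePrior:
    """Exchangeable prior summarized by ``phi = SD(tau_i - tau_j)``, i != j."""

    phi: float

    def __post_init__(self):
        if not np.isfinite(self.phi) or self.phi < 0:
            raise ValueError("phi must be finite and nonnegative")


@dataclass
class InequityResult:
    """Difference in Bayes risk between subgroup i and subgroup j.

    Positive values mean subgroup i's estimator carries the higher average
    risk; the measure is antisymmetric in (i, j).
    """

    value: float
    pair: tuple
    estimator: str
    prior: str


def _unit(g: int, G: int) -> np.ndarray:
    e = np.zeros(G)
    e[g] = 1.0
    return e


def _check_g1_warning(G: int) -> bool:
    if G < 2:
        warnings.warn("single subgroup: all inequity measures are 0 by construction")
        return True
    return False


def risk_sate(sigma_beta: float, p, tau, g: int) -> float:
    """Mean squared error of an unbiased SATE estimator as an estimate of
    subgroup g's effect: ``sigma_beta^2 + ((e_g - p)' tau)^2``.

    The quadratic form equals ``sigma_beta^2 + (tau_g - beta)^2`` with
    ``beta = p' tau``: the estimator's variance plus the squared gap between
    the subgroup effect and the overall average. ``g`` is a zero-based index.
    """
    p = np.asarray(p, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if p.shape != tau.shape:
        raise ValueError("p and tau must have the same length")
    G = len(p)
    if not 0 <= g < G:
        raise ValueError(f"subgroup index {g} out of range for G={G}")
    d = _unit(g, G) - p
    return float(sigma_beta**2 + (d @ tau) ** 2)


def inequity_sate(prior: PriorMoments, p, i: int, j: int) -> InequityResult:
    """Inequity in Bayes risk between subgroups i and j when both are handed
    the same unbiased SATE estimate:
    ``tr{((e_i - p)(e_i - p)' - (e_j - p)(e_j - p)') M}``."""
    p = np.asarray(p, dtype=float)
    G = len(p)
    if prior.n_groups != G:
        raise ValueError(f"prior is {prior.n_groups}x{prior.n_groups} but p has length {G}")
    if _check_g1_warning(G):
        return InequityResult(0.0, (i, j), "sate", "general")
    if not (0 <= i < G and 0 <= j < G):
        raise ValueError("subgroup indices out of range")
    di = _unit(i, G) - p
    dj = _unit(j, G) - p
    val = float(np.trace((np.outer(di, di) - np.outer(dj, dj)) @ prior.M))
    return InequityResult(val, (i, j), "sate", "general")


def inequity_exchangeable(prior: ExchangeablePrior, p_i: float, p_j: float) -> InequityResult:
    """Exchangeable-prior inequity of the shared SATE estimate:
    ``phi^2 (p_j - p_i)`` — proportional to the representation gap."""
    for name, v in (("p_i", p_i), ("p_j", p_j)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    val = prior.phi**2 * (p_j - p_i)
    return InequityResult(float(val), (p_i, p_j), "sate", f"exchangeable(phi={prior.phi})")


def inequity_unbiased(sigma1_sq: float, sigma2_sq: float) -> InequityResult:
    """Inequity between two unbiased subgroup-specific estimators: the
    difference of their variances ``sigma_1^2 - sigma_2^2``."""
    if sigma1_sq < 0 or sigma2_sq < 0:
        raise ValueError("variances must be nonnegative")
    return InequityResult(float(sigma1_sq - sigma2_sq), (0, 1), "unbiased-subgroup", "any")


def popoviciu_phi_bound(c: float) -> float:
    """Upper bound on phi from Popoviciu's variance inequality.

    If subgroup effects are known to differ by at most ``c`` with certainty,
    the SD of their difference is at most ``c / 2``.
    """
    if c < 0:
        raise ValueError("maximum absolute difference c must be nonnegative")
    return c / 2
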