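"""Representation-adjustment weight matrices.

A representation-adjusted ATE for subgroup g is a weighted average
``eta_g = sum_k q_gk tau_k`` of the subgroup effects, row g of a row-stochastic
matrix Q giving the subgroup composition of g's pseudo-sample. Two
constructions are provided, both governed by the heterogeneity hyperparameter
``phi`` (SD of pairwise subgroup-effect differences under an exchangeable
prior):

* **optimal** — minimizes each subgroup's Bayes risk separately,
  ``q_g = (1 - 1' W e_g)(1' W 1)^{-1} W 1 + W e_g`` with
  ``W = phi^2 (2 Sigma + phi^2 I)^{-1}``;
* **shared** — constrains every pseudo-sample to the same composition
  ``q_g = w e_g + (1 - w)(1 - e_g)/(G - 1)`` and picks the ``w`` minimizing
  the subgroup-averaged Bayes risk, ``w = 1/(1 + gamma)``.

Both shrink toward pooling as phi decreases and approach the identity
(fully stratified analysis) as phi grows or as standard errors vanish.
In the uncorrelated case the optimal construction coincides with the posterior
means of a normal hierarchical model with known hypervariance ``phi^2/2`` and
a flat prior on the hypermean (:func:`hierarchical_shrinkage_oracle`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .data import SubgroupEstimates

__all__ = [
    "WeightMatrix",
    "optimal_weights",
    "shared_weights",
    "identity_weights",
    "hierarchical_shrinkage_oracle",
]

_ROW_SUM_TOL = 1e-10


@dataclass
class WeightMatrix:
    """Row-stochastic G x G matrix of pseudo-sample subgroup probabilities.

    ``Q[g, k]`` is the probability that a member of subgroup g's
    representation-adjusted sample belongs to subgroup k; the diagonal holds
    each subgroup's self-representation.
    """

    Q: np.ndarray
    labels: list
    phi: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.labels = list(self.labels)
        G = len(self.labels)
        if self.Q.shape != (G, G):
            raise ValueError("Q must be G x G with one row per label")
        rs = self.Q.sum(axis=1)
        if np.abs(rs - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError(f"rows of Q must sum to 1 (max deviation {np.abs(rs-1).max():.2e})")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            warnings.warn("weight matrix has entries outside [0, 1] (generalized "
                          "weights; expected only with correlated estimators)")

    @property
    def self_weights(self) -> np.ndarray:
        return np.diag(self.Q).copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path, phi: float = float("nan"), method: str = "custom") -> "WeightMatrix":
        df = pd.read_csv(path, index_col="label")
        return cls(df.to_numpy(float), list(df.columns), phi=phi, method=method)


def _gls_pooling_row(cov: np.ndarray) -> np.ndarray:
    """Generalized-least-squares pooling weights Sigma^{-1} 1 / (1' Sigma^{-1} 1)."""
    G = cov.shape[0]
    one = np.ones(G)
    try:
        x = linalg.solve(cov, one, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular at phi=0; full pooling weights are undefined"
        ) from exc
    return x / (one @ x)


def optimal_weights(est: SubgroupEstimates, phi: float) -> WeightMatrix:
    """Per-subgroup Bayes-risk-minimizing weights.

    ``phi = 0`` is taken through its analytic limit — every row becomes the
    GLS pooling row (inverse-variance weights for diagonal covariance), the
    formula itself being 0/0 there. As ``phi`` grows the matrix tends to the
    identity.
    """
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    G = est.n_groups
    if phi == 0:
        row = _gls_pooling_row(est.cov)
        Q = np.tile(row, (G, 1))
        return WeightMatrix(Q, est.labels, phi=0.0, method="optimal",
                            diagnostics={"Omega": np.zeros((G, G)), "limit": "gls-pooling"})
    A = 2 * est.cov + phi**2 * np.eye(G)
    Omega = phi**2 * linalg.solve(A, np.eye(G), assume_a="pos")
    one = np.ones(G)
    Om1 = Omega @ one
    denom = one @ Om1
    Q = np.empty((G, G))
    for g in range(G):
        e = np.zeros(G)
        e[g] = 1.0
        Ome = Omega @ e
        Q[g] = (1 - one @ Ome) / denom * Om1 + Ome
    Q /= Q.sum(axis=1, keepdims=True)  # remove last-ulp drift only
    return WeightMatrix(Q, est.labels, phi=float(phi), method="optimal",
                        diagnostics={"Omega": Omega})


def shared_weights(est: SubgroupEstimates, phi: float) -> WeightMatrix:
    """Single shared pseudo-sample composition across subgroups.

    Every row has self-weight ``w = 1/(1 + gamma)`` and spreads the remaining
    mass equally over the other subgroups, with
    ``gamma = (sigma_bar^2 (G-1) - V1) / (phi^2 G / 2 + V2/(G-1) - V1)``.
    A negative ``gamma`` (possible for unusual covariances) is clamped to 0
    with a warning so that ``w`` stays in [0, 1]; a nonpositive denominator
    violates the construction's regularity condition and raises.
    """
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    G = est.n_groups
    if G < 2:
        raise ValueError("shared weights require at least two subgroups")
    Sig = est.cov
    one = np.ones(G)
    sigma_bar_sq = np.trace(Sig) / G
    V1 = sum(Sig[g] @ (one - _e(g, G)) for g in range(G)) / G  # e_g' Sig (1 - e_g)
    V2 = sum((one - _e(g, G)) @ Sig @ (one - _e(g, G)) for g in range(G)) / G
    denom = phi**2 * G / 2 + V2 / (G - 1) - V1
    if denom <= 0:
        raise ValueError("shared-weight regularity condition violated: "
                         f"phi^2 G/2 + V2/(G-1) - V1 = {denom:.3e} <= 0")
    gamma = (sigma_bar_sq * (G - 1) - V1) / denom
    if gamma < 0:
        warnings.warn(f"shared-weight gamma = {gamma:.3e} < 0; clamping to 0 "
                      "(identity weights)")
        gamma = 0.0
    w = 1.0 / (1.0 + gamma)
    Q = np.full((G, G), (1 - w) / (G - 1))
    np.fill_diagonal(Q, w)
    return WeightMatrix(Q, est.labels, phi=float(phi), method="shared",
                        diagnostics={"gamma": gamma, "w": w, "sigma_bar_sq": sigma_bar_sq,
                                     "V1": V1, "V2": V2})


def identity_weights(est: SubgroupEstimates) -> WeightMatrix:
    """Identity matrix: no adjustment, fully stratified analysis."""
    return WeightMatrix(np.eye(est.n_groups), est.labels, phi=float("inf"),
                        method="identity")


def _e(g: int, G: int) -> np.ndarray:
    e = np.zeros(G)
    e[g] = 1.0
    return e


def hierarchical_shrinkage_oracle(tau_hat, se_sq, phi: float) -> np.ndarray:
    """Posterior means from a normal hierarchical model with fixed
    hypervariance ``phi^2 / 2`` and a flat prior on the hypermean.

    Each estimate is pulled toward the precision-weighted pooled mean by
    ``B_g = (phi^2/2) / (se_g^2 + phi^2/2)``. For uncorrelated estimators this
    reproduces the optimal-weights representation-adjusted estimates exactly,
    which makes it a convenient independent cross-check; it also stands in for
    a random-effects (empirical-Bayes) comparator with the heterogeneity
    variance held fixed rather than estimated.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    se_sq = np.asarray(se_sq, dtype=float)
    if tau_hat.shape != se_sq.shape:
        raise ValueError("tau_hat and se_sq must have the same length")
    if (se_sq < 0).any():
        raise ValueError("squared standard errors must be nonnegative")
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    half_phi_sq = phi**2 / 2
    if np.isinf(phi):
        return tau_hat.copy()
    if half_phi_sq == 0:
        w = 1.0 / se_sq
        mu = (w * tau_hat).sum() / w.sum()
        return np.full_like(tau_hat, mu)
    B = half_phi_sq / (se_sq + half_phi_sq)
    mu = (B * tau_hat).sum() / B.sum()
    return B * tau_hat + (1 - B) * mu
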