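"""Unbiased subgroup ATE estimators from individual-level trial data.

Three routes to a :class:`~ratequity.data.SubgroupEstimates`: fully
stratified difference-in-means, a regression model with treatment-by-subgroup
interaction terms (covariance via contrast propagation — shared covariate
adjustment induces correlation between subgroup estimators), and an
outcome-model (g-computation) estimator built from fitted per-arm prediction
models with a bootstrap covariance. The sample ATE is the
representation-weighted average ``beta = p' tau`` of the subgroup effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import SubgroupEstimates, TrialData

__all__ = [
    "estimate_stratified",
    "estimate_interaction",
    "estimate_outcome_model",
    "sate_estimate",
]


def estimate_stratified(data: TrialData) -> SubgroupEstimates:
    """Per-subgroup difference in arm means with unpooled (Welch-type) variances.

    For subgroup g, ``tau_hat_g = mean(Y | A=1) - mean(Y | A=0)`` within the
    subgroup and ``var_g = s1^2/n1 + s0^2/n0`` with sample variances (n-1
    denominator). Estimators from disjoint strata are uncorrelated, so the
    covariance is diagonal.
    """
    G = data.n_groups
    tau = np.empty(G)
    var = np.empty(G)
    n_g = np.empty(G, dtype=int)
    for i, lab in enumerate(data.labels):
        m = data.group_mask(lab)
        y1 = data.outcome[m & (data.treatment == 1)]
        y0 = data.outcome[m & (data.treatment == 0)]
        if len(y1) == 0 or len(y0) == 0:
            raise ValueError(f"subgroup {lab!r} has an empty treatment arm")
        if len(y1) < 2 or len(y0) < 2:
            raise ValueError(f"subgroup {lab!r} has fewer than 2 records in an arm; "
                             "variance is undefined")
        tau[i] = y1.mean() - y0.mean()
        var[i] = y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)
        n_g[i] = m.sum()
    return SubgroupEstimates(labels=data.labels, tau_hat=tau, cov=np.diag(var),
                             p=n_g / n_g.sum(), n_g=n_g)


def _interaction_design(data: TrialData, covariate_names) -> tuple[np.ndarray, list[str]]:
    """Design: intercept, subgroup mains (ref = first label), covariates,
    one treatment-by-subgroup column per subgroup."""
    G = data.n_groups
    n = data.n
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    for lab in data.labels[1:]:
        cols.append(data.group_mask(lab).astype(float))
        names.append(f"group[{lab}]")
    for c in covariate_names:
        cols.append(data.covariates[c].to_numpy(float))
        names.append(c)
    for lab in data.labels:
        cols.append(data.treatment * data.group_mask(lab).astype(float))
        names.append(f"treat:group[{lab}]")
    return np.column_stack(cols), names


def estimate_interaction(data: TrialData,
                         covariate_names: list[str] | None = None) -> SubgroupEstimates:
    """Treatment-by-subgroup interaction regression, OLS.

    The model has an intercept, subgroup main effects, the named covariates,
    and one treatment-by-subgroup term per subgroup, whose coefficient is that
    subgroup's treatment effect. Estimates are linear contrasts of the fitted
    coefficients; the covariance ``C V C'`` propagates the coefficient
    covariance through the contrasts and is generally non-diagonal when
    covariates are shared across subgroups.
    """
    covariate_names = list(covariate_names or [])
    if covariate_names and data.covariates is None:
        raise ValueError("covariate_names given but data has no covariates")
    X, names = _interaction_design(data, covariate_names)
    if data.n < X.shape[1]:
        raise ValueError(f"fewer records ({data.n}) than parameters ({X.shape[1]})")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix; check subgroup arms and covariates")
    res = sm.OLS(data.outcome, X).fit()
    G = data.n_groups
    # contrast matrix selecting the treatment-by-subgroup coefficients
    C = np.zeros((G, X.shape[1]))
    for g in range(G):
        C[g, X.shape[1] - G + g] = 1.0
    tau = C @ res.params
    cov = C @ res.cov_params() @ C.T
    n_g = np.array([data.group_mask(l).sum() for l in data.labels])
    return SubgroupEstimates(labels=data.labels, tau_hat=tau, cov=cov,
                             p=n_g / n_g.sum(), n_g=n_g)


def _outcome_model_point(data: TrialData, g0, g1) -> np.ndarray:
    pred1 = np.asarray(g1(data), dtype=float)
    pred0 = np.asarray(g0(data), dtype=float)
    if not (np.isfinite(pred0).all() and np.isfinite(pred1).all()):
        raise ValueError("arm model produced non-finite predictions")
    diff = pred1 - pred0
    return np.array([diff[data.group_mask(l)].mean() for l in data.labels])


def estimate_outcome_model(data: TrialData, arm_models, n_boot: int = 1000,
                           seed: int | None = None) -> SubgroupEstimates:
    """Outcome-model (g-computation) subgroup estimator.

    ``arm_models`` is a pair ``(g0, g1)`` of callables mapping a
    :class:`TrialData` to per-record predictions of the outcome under control
    and treatment. ``tau_hat_g`` is the within-subgroup empirical mean of
    ``g1(X) - g0(X)``; the covariance is a nonparametric bootstrap over records
    (no closed form exists for a generic pair of fitted arm models).
    """
    g0, g1 = arm_models
    tau = _outcome_model_point(data, g0, g1)
    rng = np.random.default_rng(seed)
    df = data.to_dataframe()
    cov_names = list(data.covariates.columns) if data.covariates is not None else None
    boot = np.empty((n_boot, data.n_groups))
    for b in range(n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        bdf = df.iloc[idx].reset_index(drop=True)
        # resamples missing a subgroup entirely are redrawn
        while set(data.labels) - set(bdf["subgroup"]):
            idx = rng.integers(0, data.n, size=data.n)
            bdf = df.iloc[idx].reset_index(drop=True)
        bdata = TrialData.from_dataframe(bdf, covariates=cov_names, labels=data.labels)
        boot[b] = _outcome_model_point(bdata, g0, g1)
    n_g = np.array([data.group_mask(l).sum() for l in data.labels])
    return SubgroupEstimates(labels=data.labels, tau_hat=tau,
                             cov=np.cov(boot, rowvar=False),
                             p=n_g / n_g.sum(), n_g=n_g)


def sate_estimate(est: SubgroupEstimates) -> tuple[float, float]:
    """Sample ATE ``beta = p' tau_hat`` and its standard error ``sqrt(p' cov p)``."""
    beta = float(est.p @ est.tau_hat)
    se = float(np.sqrt(est.p @ est.cov @ est.p))
    return beta, se
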