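"""Containers for trial data and subgroup effect estimates.

Two kinds of input are supported: individual-level randomized-trial records
(:class:`TrialData`) and published summary-level subgroup results
(:class:`SummaryRow`), either of which yields a :class:`SubgroupEstimates`
object — the vector of unbiased subgroup ATE estimates, their covariance, and
the sample representation of each subgroup — that every downstream method
consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrialData",
    "SubgroupEstimates",
    "SummaryRow",
    "from_summaries",
    "read_summary_csv",
    "read_covariance_csv",
    "read_trial_csv",
]

# tolerance for "representations sum to one" on published, rounded proportions
_P_SUM_TOL = 0.01


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class TrialData:
    """Individual-level randomized-trial records.

    Parameters
    ----------
    outcome : array-like of float
        Observed outcome ``Y``.
    treatment : array-like of {0, 1}
        Binary treatment assignment ``A``.
    subgroup : array-like
        Subgroup label for each record; labels must come from ``labels``.
    covariates : pandas.DataFrame, optional
        Baseline covariate columns (e.g. a continuous ``X1``, a binary ``X2``).
    labels : sequence, optional
        Ordered subgroup label set; defaults to the sorted unique labels seen.
    """

    outcome: np.ndarray
    treatment: np.ndarray
    subgroup: np.ndarray
    covariates: pd.DataFrame | None = None
    labels: list = field(default=None)

    def __post_init__(self):
        self.outcome = _as_1d(self.outcome, "outcome")
        self.treatment = np.asarray(self.treatment)
        self.subgroup = np.asarray(self.subgroup)
        n = len(self.outcome)
        if len(self.treatment) != n or len(self.subgroup) != n:
            raise ValueError("outcome, treatment and subgroup must have equal length")
        if not np.isin(self.treatment, [0, 1]).all():
            raise ValueError("treatment must be binary 0/1")
        self.treatment = self.treatment.astype(int)
        if self.labels is None:
            self.labels = sorted(pd.unique(self.subgroup).tolist())
        else:
            self.labels = list(self.labels)
            unknown = set(pd.unique(self.subgroup)) - set(self.labels)
            if unknown:
                raise ValueError(f"records carry undeclared subgroup labels: {sorted(unknown)}")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != n:
                raise ValueError("covariates must have one row per record")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "outcome",
                       treatment: str = "treatment", subgroup: str = "subgroup",
                       covariates: list[str] | None = None,
                       labels=None) -> "TrialData":
        cov = df[list(covariates)] if covariates else None
        return cls(df[outcome].to_numpy(float), df[treatment].to_numpy(),
                   df[subgroup].to_numpy(), covariates=cov, labels=labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"outcome": self.outcome, "treatment": self.treatment,
                           "subgroup": self.subgroup})
        if self.covariates is not None:
            for c in self.covariates.columns:
                df[c] = self.covariates[c].to_numpy()
        return df

    def group_mask(self, label) -> np.ndarray:
        return self.subgroup == label


@dataclass
class SubgroupEstimates:
    """Unbiased subgroup ATE estimates with covariance and representation.

    Attributes
    ----------
    labels : list
        Ordered subgroup names (length ``G``).
    tau_hat : (G,) ndarray
        Point estimates of the subgroup sample ATEs, in outcome units.
    cov : (G, G) ndarray
        Covariance matrix of the estimators (diagonal entries are the squared
        standard errors).
    p : (G,) ndarray
        Sample representation of each subgroup; entries in [0, 1], sum to 1.
    n_g : (G,) ndarray or None
        Subgroup sample counts when individual-level data were used.
    """

    labels: list
    tau_hat: np.ndarray
    cov: np.ndarray
    p: np.ndarray
    n_g: np.ndarray | None = None

    def __post_init__(self):
        self.labels = list(self.labels)
        self.tau_hat = _as_1d(self.tau_hat, "tau_hat")
        self.p = _as_1d(self.p, "p")
        self.cov = np.asarray(self.cov, dtype=float)
        G = len(self.labels)
        if G < 2:
            raise ValueError("at least two subgroups are required")
        if len(self.tau_hat) != G or len(self.p) != G or self.cov.shape != (G, G):
            raise ValueError("labels, tau_hat, cov and p must all have matching size G")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")
        eigmin = np.linalg.eigvalsh((self.cov + self.cov.T) / 2).min()
        if eigmin < -1e-8 * max(1.0, np.abs(self.cov).max()):
            raise ValueError("covariance matrix must be positive semidefinite")
        if (self.p < -1e-12).any() or (self.p > 1 + 1e-12).any():
            raise ValueError("representation entries must lie in [0, 1]")
        psum = self.p.sum()
        if abs(psum - 1.0) > _P_SUM_TOL:
            raise ValueError(f"representation must sum to 1 (got {psum:.4f})")
        if abs(psum - 1.0) > 1e-9:
            logger.warning("renormalizing representation vector (sum %.4f)", psum)
            self.p = self.p / psum
        if self.n_g is not None:
            self.n_g = np.asarray(self.n_g)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def se(self) -> np.ndarray:
        """Standard errors (square roots of the covariance diagonal)."""
        return np.sqrt(np.diag(self.cov))


@dataclass
class SummaryRow:
    """One published subgroup result: estimate, confidence interval, representation."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    representation: float
    level: float = 0.95

    def __post_init__(self):
        if not self.ci_high > self.ci_low:
            raise ValueError(f"{self.label}: ci_high must exceed ci_low")
        if not 0 < self.level < 1:
            raise ValueError(f"{self.label}: confidence level must be in (0, 1)")


def from_summaries(rows: list[SummaryRow], cov: np.ndarray | None = None) -> SubgroupEstimates:
    """Build :class:`SubgroupEstimates` from published point estimates and CIs.

    Standard errors are recovered from the interval width,
    ``SE = (ci_high - ci_low) / (2 z)`` with ``z`` the exact standard-normal
    quantile for the stated level (1.959964 at 95%). The covariance defaults to
    ``diag(SE^2)`` — published subgroup results rarely report correlations — but
    a full matrix may be supplied when the estimators are known to be
    correlated.
    """
    if not rows:
        raise ValueError("no summary rows supplied")
    levels = {r.level for r in rows}
    if len(levels) > 1:
        raise ValueError(f"rows carry mixed confidence levels: {sorted(levels)}")
    level = levels.pop()
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.array([(r.ci_high - r.ci_low) / (2 * z) for r in rows])
    p = np.array([r.representation for r in rows], dtype=float)
    if cov is None:
        cov = np.diag(se**2)
    return SubgroupEstimates(
        labels=[r.label for r in rows],
        tau_hat=np.array([r.estimate for r in rows], dtype=float),
        cov=np.asarray(cov, dtype=float),
        p=p,
    )


def read_summary_csv(path) -> list[SummaryRow]:
    """Read summary rows from CSV with columns
    label, estimate, ci_low, ci_high, representation [, level]."""
    df = pd.read_csv(path)
    required = {"label", "estimate", "ci_low", "ci_high", "representation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        kwargs = dict(label=str(r["label"]), estimate=float(r["estimate"]),
                      ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
                      representation=float(r["representation"]))
        if "level" in df.columns and not pd.isna(r["level"]):
            kwargs["level"] = float(r["level"])
        rows.append(SummaryRow(**kwargs))
    return rows


def read_covariance_csv(path, labels: list[str]) -> np.ndarray:
    """Read a G x G covariance CSV whose header row matches ``labels``."""
    df = pd.read_csv(path)
    cols = [str(c) for c in df.columns]
    if cols != [str(l) for l in labels]:
        raise ValueError(f"covariance CSV header {cols} does not match labels {labels}")
    M = df.to_numpy(float)
    if M.shape != (len(labels), len(labels)):
        raise ValueError("covariance CSV must be square with one row per label")
    return M


def read_trial_csv(path, covariates: list[str] | None = None, labels=None) -> TrialData:
    """Read individual-level records (columns outcome, treatment, subgroup, covariates)."""
    return TrialData.from_dataframe(pd.read_csv(path), covariates=covariates, labels=labels)
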