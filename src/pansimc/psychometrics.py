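"""Instrument validation: correlations, KMO, Bartlett, Kaiser, loadings.

The validation stage asks whether item-level data are factorable and how
many factors to keep:

* **KMO** (Kaiser-Meyer-Olkin sampling adequacy):
  ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j, where q_ij
  are the anti-image partial correlations ``q_ij = -s_ij / sqrt(s_ii s_jj)``
  with S = R^-1. Values near 1 favour factor analysis.
* **Bartlett's sphericity test**: ``chi2 = -(n - 1 - (2p + 5)/6) ln det R``
  with ``df = p(p-1)/2``, against the asymptotic chi-square reference.
* **Kaiser criterion**: retain eigenvalues of R strictly greater than 1.
* **Loadings**: principal-component loadings (eigenvectors scaled by
  sqrt(eigenvalue)) with varimax rotation for k >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CorrelationMatrix",
    "FactorReport",
    "correlation_matrix",
    "kmo",
    "bartlett",
    "kaiser_retain",
    "variance_explained",
    "loadings",
    "factor_report",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson correlation matrix with labels."""

    values: np.ndarray
    labels: tuple[str, ...]
    n_obs: int | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.values, dtype=float)
        p = r.shape[0]
        if r.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if len(self.labels) != p:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")
        object.__setattr__(self, "values", r)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def correlation_matrix(
    data: pd.DataFrame, columns: list[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlations over listwise-complete rows.

    Accepts any numeric DataFrame (item responses or a score table's
    ``.scores``). Raises for constant columns, naming the offender.
    """
    if hasattr(data, "scores"):  # accept a ScoreTable directly
        data = data.scores
    df = data[columns] if columns is not None else data
    complete = df.dropna().astype(float)
    if complete.shape[0] < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    sd = complete.std(ddof=1)
    for col, s in sd.items():
        if s == 0:
            raise ValueError(f"column {col!r} is constant; no correlation defined")
    r = np.corrcoef(complete.to_numpy().T)
    # clamp float noise so invariants hold exactly
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, labels=tuple(complete.columns), n_obs=complete.shape[0])


def _offdiag_mask(p: int) -> np.ndarray:
    return ~np.eye(p, dtype=bool)


def kmo(R: CorrelationMatrix | np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1]."""
    r = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    p = r.shape[0]
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "correlation matrix is singular; consider ridge-regularizing "
            "before computing KMO (not applied automatically)"
        ) from None
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d  # anti-image partial correlations (off-diagonal)
    mask = _offdiag_mask(p)
    r2 = (r[mask] ** 2).sum()
    q2 = (q[mask] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett(R: CorrelationMatrix | np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: (chi2, df, p-value).

    Tests whether R is the identity; requires n > p and positive definite R.
    """
    r = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    p = r.shape[0]
    if n <= p:
        raise ValueError(f"sample size {n} must exceed the number of variables {p}")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(chi2_dist.sf(chi2, df))
    return float(chi2), int(df), pval


def kaiser_retain(eigenvalues: np.ndarray) -> int:
    """Number of correlation-matrix eigenvalues strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Cumulative proportion of total variance per retained eigenvalue.

    The trace of a correlation matrix is p, so proportions are cumulative
    sums over p; the final entry is 1.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    return np.cumsum(ev) / ev.sum()


def _eigen_desc(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def loadings(R: CorrelationMatrix | np.ndarray, k: int) -> np.ndarray:
    """p x k principal-component loadings, varimax-rotated for k >= 2.

    Columns are ordered by explained variance; communalities (row sums of
    squared loadings) are preserved by the orthogonal rotation.
    """
    r = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    p = r.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    w, v = _eigen_desc(r)
    w = np.clip(w, 0.0, None)
    load = v[:, :k] * np.sqrt(w[:k])
    if k >= 2:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        load, _ = rotate_factors(load, "varimax")
        # reorder rotated columns by explained variance, largest first
        order = np.argsort((load**2).sum(axis=0))[::-1]
        load = load[:, order]
    return load


@dataclass
class FactorReport:
    """Bundle of validation statistics for one instrument's items."""

    labels: tuple[str, ...]
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    n_retained: int
    loadings: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "kmo": self.kmo,
            "bartlett": {
                "chi2": self.bartlett_chi2,
                "df": self.bartlett_df,
                "p": self.bartlett_p,
            },
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "n_retained": self.n_retained,
            "loadings": self.loadings.tolist(),
            "n_obs": self.n_obs,
        }


def factor_report(data: pd.DataFrame, columns: list[str] | None = None) -> FactorReport:
    """Full validation pipeline on item-level data: correlations, KMO,
    Bartlett, eigenvalues, Kaiser retention, rotated loadings."""
    R = correlation_matrix(data, columns)
    w, _ = _eigen_desc(R.values)
    k = max(kaiser_retain(w), 1)
    c2, df, pv = bartlett(R, R.n_obs or 0)
    return FactorReport(
        labels=R.labels,
        eigenvalues=w,
        variance_explained=variance_explained(w),
        n_retained=kaiser_retain(w),
        loadings=loadings(R, k),
        kmo=kmo(R),
        bartlett_chi2=c2,
        bartlett_df=df,
        bartlett_p=pv,
        n_obs=R.n_obs or 0,
    )
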