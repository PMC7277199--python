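"""Synthetic questionnaire cohorts via a Gaussian copula.

Real item-level responses from the study population are not deposited, so
every downstream stage is exercised on simulated cohorts instead. The
generator draws one latent normal variable per subscale with a target
scale-level correlation structure (defaulting to the correlation matrix
reported for the study's nine subscales), gives each item a latent
``lambda * factor + sqrt(1 - lambda^2) * noise`` (common loading 0.7), and
thresholds item latents into ordinal Likert categories at equal-mass normal
quantiles. A nonnegative ``ceiling_skew`` shifts all thresholds down so the
top response category captures more mass — emulating the ceiling effect that
makes real score distributions non-Gaussian. Reverse-keyed items emit the
reversed raw response so that *scored* subscales track the latent targets
with a positive sign.

What this emulates: ordinal items, subscale-level correlation structure,
ceiling skew, a fixed cohort size (default 413, the study's sample). What it
does not: item-level residual correlations, differential item difficulty,
nonresponse mechanisms, demographic structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instruments import (
    InstrumentSpec,
    ResponseMatrix,
    SUBSCALE_COLUMNS,
    builtin_specs,
)

__all__ = [
    "CohortSpec",
    "default_scale_correlation",
    "generate_latent",
    "discretize_to_items",
    "generate_cohort",
]

# Scale-level Pearson correlations among the nine subscales, as reported for
# the study cohort (order: SP, AE, IP, BP, CM, R, APGAR, NSI, PI).
_CORR_ORDER = (
    "BSSA_SP",
    "BSSA_AE",
    "BSSA_IP",
    "BQREB_BP",
    "BQREB_CM",
    "BQREB_R",
    "APGAR",
    "PANSI_NSI",
    "PANSI_PI",
)
_CORR_LOWER = [
    [1.000],
    [0.122, 1.000],
    [0.148, 0.490, 1.000],
    [-0.067, -0.116, -0.094, 1.000],
    [-0.099, -0.055, -0.034, 0.409, 1.000],
    [0.012, 0.041, 0.016, 0.288, 0.207, 1.000],
    [0.049, -0.037, 0.051, -0.021, -0.091, 0.015, 1.000],
    [0.027, 0.024, 0.012, -0.014, -0.015, 0.032, -0.095, 1.000],
    [-0.006, 0.033, -0.061, -0.053, -0.020, 0.021, -0.114, 0.558, 1.000],
]


def default_scale_correlation() -> pd.DataFrame:
    """Default scale-level latent correlation target (nine subscales)."""
    p = len(_CORR_ORDER)
    m = np.eye(p)
    for i, row in enumerate(_CORR_LOWER):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=list(_CORR_ORDER), columns=list(_CORR_ORDER))


@dataclass
class CohortSpec:
    """Settings for one synthetic cohort.

    Parameters
    ----------
    n_respondents
        Cohort size; defaults to 413, matching the study sample.
    latent_corr
        Scale-level correlation target (labels x labels DataFrame); defaults
        to the reported study matrix.
    loading
        Common item loading on its subscale factor (0.7 default).
    ceiling_skew
        >= 0; shifts every item threshold down by this many latent SDs,
        piling response mass onto the top category.
    seed
        RNG seed; identical spec + seed reproduces the cohort bitwise.
    """

    n_respondents: int = 413
    latent_corr: pd.DataFrame | None = None
    loading: float = 0.7
    ceiling_skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not 0 < self.loading < 1:
            raise ValueError("loading must be in (0, 1)")
        if self.ceiling_skew < 0:
            raise ValueError("ceiling_skew must be >= 0")
        if self.latent_corr is None:
            self.latent_corr = default_scale_correlation()

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "latent_corr": {
                "labels": list(self.latent_corr.columns),
                "values": self.latent_corr.to_numpy().tolist(),
            },
            "loading": self.loading,
            "ceiling_skew": self.ceiling_skew,
            "seed": self.seed,
        }


def generate_latent(
    corr: pd.DataFrame | np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n iid multivariate-normal rows with the given correlation.

    Uses the symmetric square root of the correlation matrix (eigendecomposition),
    which handles positive-semidefinite targets; raises for an indefinite
    matrix, naming the offending eigenvalue.
    """
    c = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(c)
    if w.min() < -1e-10:
        raise ValueError(f"correlation matrix is not PSD (eigenvalue {w.min():.3e})")
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    z = rng.standard_normal((n, c.shape[0]))
    return z @ root.T


def _item_thresholds(n_categories: int, ceiling_skew: float) -> np.ndarray:
    """Strictly increasing latent cut points for an item.

    Equal-mass standard-normal quantiles, shifted down by ``ceiling_skew``.
    """
    if n_categories < 2:
        raise ValueError("an item needs at least 2 response categories")
    qs = np.arange(1, n_categories) / n_categories
    return norm.ppf(qs) - ceiling_skew


def discretize_to_items(
    latent: np.ndarray, thresholds: list[np.ndarray], mins: list[int]
) -> np.ndarray:
    """Threshold item latents (n x k) into integer responses.

    ``thresholds[j]`` are the increasing cut points for item j (``c`` cuts
    give ``c + 1`` categories starting at ``mins[j]``).
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape[1] != len(thresholds) or len(thresholds) != len(mins):
        raise ValueError("latent columns, thresholds and mins must align")
    out = np.empty(latent.shape, dtype=np.int64)
    for j, (cuts, lo) in enumerate(zip(thresholds, mins)):
        cuts = np.asarray(cuts, dtype=float)
        if cuts.size and np.any(np.diff(cuts) <= 0):
            raise ValueError(f"item {j}: thresholds must be strictly increasing")
        out[:, j] = lo + np.searchsorted(cuts, latent[:, j], side="left")
    return out


def generate_cohort(spec: CohortSpec) -> ResponseMatrix:
    """Generate a complete 39-item response matrix scoreable downstream.

    Larger latent correlation between two subscales yields larger Pearson
    correlation between their scores (attenuated by discretization).
    """
    rng = np.random.default_rng(spec.seed)
    instruments = builtin_specs()
    labels = list(spec.latent_corr.columns)
    factors = generate_latent(spec.latent_corr, spec.n_respondents, rng)
    lam = spec.loading
    resid = np.sqrt(1.0 - lam * lam)

    columns: dict[str, np.ndarray] = {}
    for inst in instruments.values():
        for subscale, members in inst.subscales.items():
            f = factors[:, labels.index(subscale)]
            for item_id, reversed_ in members:
                item = inst.item(item_id)
                ncat = item.max_response - item.min_response + 1
                y = lam * f + resid * rng.standard_normal(spec.n_respondents)
                cuts = _item_thresholds(ncat, spec.ceiling_skew)
                keyed = discretize_to_items(
                    y[:, None], [cuts], [item.min_response]
                )[:, 0]
                raw = inst.reverse(item_id, keyed) if reversed_ else keyed
                columns[inst.column(item_id)] = raw

    ordered = []
    for inst in instruments.values():
        ordered.extend(inst.columns)
    df = pd.DataFrame({c: columns[c] for c in ordered})
    df.index = pd.RangeIndex(spec.n_respondents, name="respondent")
    return ResponseMatrix(df)
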