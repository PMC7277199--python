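"""Binned joint and conditional probability tables from chain samples.

Each subscale's score range is split into three closed integer intervals
(the published risk-table grids, e.g. PANSI-NSI into (8,19), (20,29),
(30,40)). Real-valued chain states are assigned to cells by midpoint cuts
between adjacent intervals — the boundary between (3,8) and (9,13) sits at
8.5 — and the outer bins extend to +/- infinity so every sample lands in
exactly one cell and counts always sum to the sample size, even though the
KDE leaks mass outside the valid score rectangle.

Both the joint table (cells sum to 1) and the table conditioned on the
factor axis (each row renormalized) are provided; the text of the source
analysis mixes the two readings, so callers get both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .instruments import PANSI_SUBSCALES, SUBSCALE_COLUMNS
from .kde import KdeModel, cell_mass

__all__ = [
    "BinGrid",
    "ProbabilityTable",
    "BUILTIN_BINS",
    "builtin_grid",
    "bin_samples",
    "joint_probabilities",
    "conditional_probabilities",
    "expected_joint_from_kde",
    "headline_risk",
    "total_variation",
]

Interval = tuple[int, int]

#: three-bin grids per subscale (closed integer intervals over the score range)
BUILTIN_BINS: dict[str, tuple[Interval, ...]] = {
    "PANSI_NSI": ((8, 19), (20, 29), (30, 40)),
    "PANSI_PI": ((6, 14), (15, 22), (23, 30)),
    "BSSA_SP": ((3, 8), (9, 13), (14, 18)),
    "BSSA_AE": ((2, 5), (6, 9), (10, 12)),
    "BSSA_IP": ((5, 13), (14, 21), (22, 30)),
    "BQREB_BP": ((4, 8), (9, 12), (13, 16)),
    "BQREB_CM": ((3, 6), (7, 9), (10, 12)),
    "BQREB_R": ((3, 6), (7, 9), (10, 12)),
    "APGAR": ((0, 3), (4, 7), (8, 10)),
}


#: default "adverse" bin indices per subscale for risk summaries: the lowest
#: bin for protective constructs (school adjustment, family function,
#: positive ideation — low scores are bad) and the highest bin for risk
#: constructs (eating-behavior factors and negative ideation, where the
#: moderate and high bins together flag developing ideation)
ADVERSE_BINS: dict[str, tuple[int, ...]] = {
    "BSSA_SP": (0,),
    "BSSA_AE": (0,),
    "BSSA_IP": (0,),
    "APGAR": (0,),
    "BQREB_BP": (2,),
    "BQREB_CM": (2,),
    "BQREB_R": (2,),
    "PANSI_NSI": (1, 2),
    "PANSI_PI": (0,),
}


@dataclass(frozen=True)
class BinGrid:
    """Cell grid over a (factor, PANSI) score pair."""

    axis1_bins: tuple[Interval, ...]
    axis2_bins: tuple[Interval, ...]
    axis1_label: str = "factor"
    axis2_label: str = "pansi"

    def __post_init__(self) -> None:
        for bins, label in ((self.axis1_bins, self.axis1_label), (self.axis2_bins, self.axis2_label)):
            if not bins:
                raise ValueError(f"{label}: empty bin list")
            prev_hi = None
            for lo, hi in bins:
                if lo > hi:
                    raise ValueError(f"{label}: bad interval ({lo},{hi})")
                if prev_hi is not None and lo <= prev_hi:
                    raise ValueError(f"{label}: intervals not disjoint/ascending")
                prev_hi = hi

    @staticmethod
    def _cuts(bins: tuple[Interval, ...]) -> np.ndarray:
        """Midpoint cut positions between adjacent intervals."""
        return np.array(
            [(bins[i][1] + bins[i + 1][0]) / 2.0 for i in range(len(bins) - 1)]
        )

    @property
    def axis1_cuts(self) -> np.ndarray:
        return self._cuts(self.axis1_bins)

    @property
    def axis2_cuts(self) -> np.ndarray:
        return self._cuts(self.axis2_bins)

    def cell_edges(self, axis: int, index: int) -> tuple[float, float]:
        """Cell boundaries on one axis with outer bins extended to +/- inf."""
        cuts = self.axis1_cuts if axis == 0 else self.axis2_cuts
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        return float(edges[index]), float(edges[index + 1])

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.axis1_bins), len(self.axis2_bins)

    def labels(self, axis: int) -> list[str]:
        bins = self.axis1_bins if axis == 0 else self.axis2_bins
        return [f"({lo},{hi})" for lo, hi in bins]


def builtin_grid(factor: str, pansi: str) -> BinGrid:
    """The published grid for a (factor subscale, PANSI subscale) pair."""
    for name in (factor, pansi):
        if name not in BUILTIN_BINS:
            raise KeyError(
                f"unknown subscale {name!r}; known: {sorted(BUILTIN_BINS)}"
            )
    if pansi not in PANSI_SUBSCALES:
        raise ValueError(f"second axis must be a PANSI subscale, got {pansi!r}")
    return BinGrid(
        axis1_bins=BUILTIN_BINS[factor],
        axis2_bins=BUILTIN_BINS[pansi],
        axis1_label=factor,
        axis2_label=pansi,
    )


@dataclass
class ProbabilityTable:
    """Cell probabilities over a :class:`BinGrid`.

    ``kind`` is ``"joint"`` (all cells sum to 1) or ``"conditional"``
    (each factor-axis row sums to 1; rows with zero joint mass carry NaN and
    are listed in ``zero_rows``).
    """

    grid: BinGrid
    cell_probs: np.ndarray
    n_samples: int
    kind: str = "joint"
    zero_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_probs = np.asarray(self.cell_probs, dtype=float)
        if self.cell_probs.shape != self.grid.shape:
            raise ValueError("cell_probs shape does not match grid")
        if self.kind not in ("joint", "conditional"):
            raise ValueError("kind must be 'joint' or 'conditional'")
        finite = self.cell_probs[np.isfinite(self.cell_probs)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("cell probabilities outside [0, 1]")
        if self.kind == "joint":
            if abs(np.nansum(self.cell_probs) - 1.0) > 1e-12:
                raise ValueError("joint table does not sum to 1")
        else:
            rows = np.nansum(self.cell_probs, axis=1)
            for i, s in enumerate(rows):
                if i in self.zero_rows:
                    continue
                if abs(s - 1.0) > 1e-12:
                    raise ValueError(f"conditional row {i} sums to {s}, not 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cell_probs,
            index=pd.Index(self.grid.labels(0), name=self.grid.axis1_label),
            columns=pd.Index(self.grid.labels(1), name=self.grid.axis2_label),
        )

    def to_csv(self, path: str | Path, decimals: int | None = None) -> None:
        df = self.to_dataframe()
        if decimals is not None:
            df = df.round(decimals)
        df.to_csv(path, float_format=None if decimals is None else f"%.{decimals}f")


def bin_samples(samples: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Count samples per grid cell; every sample lands in exactly one cell."""
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("samples must be a nonempty (m, 2) array")
    i1 = np.digitize(pts[:, 0], grid.axis1_cuts)
    i2 = np.digitize(pts[:, 1], grid.axis2_cuts)
    counts = np.zeros(grid.shape, dtype=np.int64)
    np.add.at(counts, (i1, i2), 1)
    return counts


def joint_probabilities(counts: np.ndarray, grid: BinGrid) -> ProbabilityTable:
    """Turn a cell-count matrix into a joint probability table."""
    counts = np.asarray(counts)
    m = int(counts.sum())
    if m < 1:
        raise ValueError("no samples to normalize")
    probs = counts / m
    # absorb float round-off so the sum-to-1 invariant holds exactly enough
    probs = probs / probs.sum()
    return ProbabilityTable(grid=grid, cell_probs=probs, n_samples=m, kind="joint")


def conditional_probabilities(table: ProbabilityTable) -> ProbabilityTable:
    """Condition on the factor axis: each row renormalized by its mass.

    Idempotent: conditioning a conditional table returns an equal table.
    """
    probs = np.array(table.cell_probs, dtype=float)
    row_mass = np.nansum(probs, axis=1)
    zero_rows = [i for i, s in enumerate(row_mass) if s == 0 or not np.isfinite(s)]
    out = np.full_like(probs, np.nan)
    for i, s in enumerate(row_mass):
        if i not in zero_rows:
            out[i] = probs[i] / s
    return ProbabilityTable(
        grid=table.grid,
        cell_probs=out,
        n_samples=table.n_samples,
        kind="conditional",
        zero_rows=zero_rows,
    )


def expected_joint_from_kde(model: KdeModel, grid: BinGrid) -> ProbabilityTable:
    """Exact joint table implied by a KDE: per-cell Gaussian rectangle mass.

    The product kernel integrates in closed form over each (infinite-edged)
    cell, giving the reference distribution a well-mixed chain's binned
    samples should approach.
    """
    r, c = grid.shape
    probs = np.empty((r, c))
    for i in range(r):
        xr = grid.cell_edges(0, i)
        for j in range(c):
            probs[i, j] = cell_mass(model, xr, grid.cell_edges(1, j))
    probs = probs / probs.sum()
    return ProbabilityTable(grid=grid, cell_probs=probs, n_samples=model.n, kind="joint")


def _bin_indices(bins: tuple[Interval, ...], wanted: Iterable) -> list[int]:
    idx = []
    for b in wanted:
        if isinstance(b, (int, np.integer)):
            if not 0 <= b < len(bins):
                raise KeyError(f"bin index {b} out of range")
            idx.append(int(b))
        else:
            t = (int(b[0]), int(b[1]))
            if t not in bins:
                raise KeyError(f"interval {t} not in grid bins {bins}")
            idx.append(bins.index(t))
    return idx


def headline_risk(
    table: ProbabilityTable,
    adverse_factor_bins: Sequence,
    adverse_pansi_bins: Sequence,
) -> float:
    """Summary risk figure for a score pair.

    Convention: condition on the factor axis, then take the **maximum over
    the adverse factor bins of the conditional probability mass on the
    adverse PANSI bins** — "up to an X% probability of developing suicidal
    ideation given an adverse factor score". Bins may be given as indices or
    as (lo, hi) interval tuples of the grid. This is this package's own
    documented reduction; the original analysis does not state one.
    """
    if not len(adverse_factor_bins) or not len(adverse_pansi_bins):
        raise ValueError("adverse bin sets must be nonempty")
    fi = _bin_indices(table.grid.axis1_bins, adverse_factor_bins)
    pi = _bin_indices(table.grid.axis2_bins, adverse_pansi_bins)
    cond = table if table.kind == "conditional" else conditional_probabilities(table)
    best = 0.0
    for i in fi:
        if i in cond.zero_rows:
            continue
        best = max(best, float(np.nansum(cond.cell_probs[i, pi])))
    return best


def total_variation(a: ProbabilityTable, b: ProbabilityTable) -> float:
    """Total-variation distance between two joint tables on the same grid."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("tables are on different grids")
    return float(0.5 * np.abs(a.cell_probs - b.cell_probs).sum())
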