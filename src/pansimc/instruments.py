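"""Psychometric instruments: declarative specs and item-to-subscale scoring.

Four self-report instruments are built in:

* **PANSI** — Positive and Negative Suicide Ideation inventory. 14 items on a
  1–5 Likert scale, split into a Negative Suicide Ideation subscale
  (NSI, 8 items, score range 8–40) and a Positive Ideation subscale
  (PI, 6 items, range 6–30). High NSI / low PI indicates suicide risk.
* **APGAR** — family-function screen (Adaptability, Partnership, Growth,
  Affection, Resolve). 5 items scored 0–2, total 0–10, with dysfunction
  categories (0–3 severe, 4–6 moderate, 7–10 mild).
* **BSSA-10** — Brief Scale of School Adjustment. 10 items on a 1–6 scale,
  items 6–10 reverse-keyed. Subscales: Scholarly Performance (SP, items
  1, 2, 5), Academic Expectations (AE, items 3, 4), Integration Problems
  (IP, items 6–10). High scores uniformly mean better adjustment.
* **BQREB** — Brief Questionnaire of Risk Eating Behaviors. 10 items on a
  1–4 scale with a three-factor structure: Binge-purge (BP, 4 items),
  Compensatory Measures (CM, 3 items), Restriction (R, 3 items).

Scoring is a plain sum of item responses, with reverse-keyed items mapped
through ``(min + max) - raw`` before summation. Respondents missing any item
of a subscale are excluded listwise from that subscale (sums over partial
item sets are not comparable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "InstrumentSpec",
    "ResponseMatrix",
    "ScoreTable",
    "ValidationReport",
    "builtin_specs",
    "score_subscale",
    "score_all",
    "classify_apgar",
    "validate_responses",
    "SUBSCALE_COLUMNS",
    "PANSI_SUBSCALES",
    "FACTOR_SUBSCALES",
]

#: canonical subscale column order used in score tables and CSV output
SUBSCALE_COLUMNS = (
    "PANSI_NSI",
    "PANSI_PI",
    "APGAR",
    "BSSA_SP",
    "BSSA_AE",
    "BSSA_IP",
    "BQREB_BP",
    "BQREB_CM",
    "BQREB_R",
)

PANSI_SUBSCALES = ("PANSI_NSI", "PANSI_PI")
FACTOR_SUBSCALES = (
    "BSSA_SP",
    "BSSA_AE",
    "BSSA_IP",
    "BQREB_BP",
    "BQREB_CM",
    "BQREB_R",
    "APGAR",
)


@dataclass(frozen=True)
class Item:
    """A single questionnaire item with its admissible response range."""

    item_id: int
    min_response: int
    max_response: int

    def __post_init__(self) -> None:
        if self.min_response >= self.max_response:
            raise ValueError(
                f"item {self.item_id}: min_response must be < max_response"
            )


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of an instrument.

    Parameters
    ----------
    name
        Display name (e.g. ``"BSSA-10"``).
    column_prefix
        Prefix for CSV column names (``"BSSA"`` gives ``BSSA_1 ... BSSA_10``).
    items
        Ordered items, 1-based ids matching the published item numbering.
    subscales
        Map ``subscale_column -> ((item_id, reversed), ...)``. Reversed items
        are recoded ``(min + max) - raw`` before summation.
    categories
        Optional ordered ``((lo, hi), label)`` intervals over the total score.
    """

    name: str
    column_prefix: str
    items: tuple[Item, ...]
    subscales: Mapping[str, tuple[tuple[int, bool], ...]]
    categories: tuple[tuple[tuple[int, int], str], ...] | None = None

    def __post_init__(self) -> None:
        ids = {it.item_id for it in self.items}
        if len(ids) != len(self.items):
            raise ValueError(f"{self.name}: duplicate item ids")
        for sub, members in self.subscales.items():
            for item_id, _ in members:
                if item_id not in ids:
                    raise ValueError(
                        f"{self.name}.{sub}: unknown item id {item_id}"
                    )
        if self.categories is not None:
            prev_hi = None
            for (lo, hi), _ in self.categories:
                if lo > hi:
                    raise ValueError(f"{self.name}: bad category interval ({lo},{hi})")
                if prev_hi is not None and lo <= prev_hi:
                    raise ValueError(f"{self.name}: category intervals overlap")
                prev_hi = hi

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"{self.name}: no item {item_id}")

    def column(self, item_id: int) -> str:
        return f"{self.column_prefix}_{item_id}"

    @property
    def columns(self) -> list[str]:
        return [self.column(it.item_id) for it in self.items]

    def reverse(self, item_id: int, value: int | np.ndarray):
        """Reverse-key a raw response: ``(min + max) - raw``. An involution."""
        it = self.item(item_id)
        return it.min_response + it.max_response - value

    def subscale_range(self, subscale: str) -> tuple[int, int]:
        """(min, max) attainable score; reversal maps [min,max] onto itself."""
        members = self._members(subscale)
        lo = sum(self.item(i).min_response for i, _ in members)
        hi = sum(self.item(i).max_response for i, _ in members)
        return lo, hi

    def _members(self, subscale: str) -> tuple[tuple[int, bool], ...]:
        try:
            return tuple(self.subscales[subscale])
        except KeyError:
            raise KeyError(
                f"{self.name}: unknown subscale {subscale!r}; "
                f"known: {sorted(self.subscales)}"
            ) from None


# Default PANSI keying follows the original instrument's published assignment;
# the split is configurable because the source study does not print it.
_DEFAULT_PANSI_NSI = (1, 2, 3, 5, 6, 7, 9, 11)
_DEFAULT_PANSI_PI = (4, 8, 10, 12, 13, 14)

# Default BQREB factor assignment (the published item map is not available):
# BP = items 1-4, CM = 5-7, R = 8-10.
_DEFAULT_BQREB = {
    "BQREB_BP": (1, 2, 3, 4),
    "BQREB_CM": (5, 6, 7),
    "BQREB_R": (8, 9, 10),
}

APGAR_CATEGORIES = (
    ((0, 3), "severe dysfunction"),
    ((4, 6), "moderate dysfunction"),
    ((7, 10), "mild dysfunction"),
)


def builtin_specs(
    pansi_nsi_items: Sequence[int] | None = None,
    bqreb_items: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, InstrumentSpec]:
    """Return the four built-in instrument specs keyed by name.

    Parameters
    ----------
    pansi_nsi_items
        Item ids forming the PANSI negative-ideation subscale (8 of 14);
        the remaining six form the positive-ideation subscale.
    bqreb_items
        Override for the BQREB factor -> item-id map (keys ``BQREB_BP``,
        ``BQREB_CM``, ``BQREB_R``).
    """
    nsi = tuple(pansi_nsi_items) if pansi_nsi_items is not None else _DEFAULT_PANSI_NSI
    if len(nsi) != 8:
        raise ValueError("PANSI NSI subscale must have 8 items")
    pi = tuple(i for i in range(1, 15) if i not in nsi)

    pansi = InstrumentSpec(
        name="PANSI",
        column_prefix="PANSI",
        items=tuple(Item(i, 1, 5) for i in range(1, 15)),
        subscales={
            "PANSI_NSI": tuple((i, False) for i in nsi),
            "PANSI_PI": tuple((i, False) for i in pi),
        },
    )
    apgar = InstrumentSpec(
        name="APGAR",
        column_prefix="APGAR",
        items=tuple(Item(i, 0, 2) for i in range(1, 6)),
        subscales={"APGAR": tuple((i, False) for i in range(1, 6))},
        categories=APGAR_CATEGORIES,
    )
    bssa = InstrumentSpec(
        name="BSSA-10",
        column_prefix="BSSA",
        items=tuple(Item(i, 1, 6) for i in range(1, 11)),
        subscales={
            "BSSA_SP": ((1, False), (2, False), (5, False)),
            "BSSA_AE": ((3, False), (4, False)),
            # items 6-10 are written in an inverse sense: reverse-keyed so
            # that a high IP score means good integration
            "BSSA_IP": tuple((i, True) for i in range(6, 11)),
        },
    )
    bq = dict(_DEFAULT_BQREB)
    if bqreb_items is not None:
        bq.update({k: tuple(v) for k, v in bqreb_items.items()})
        assigned = sorted(i for v in bq.values() for i in v)
        if assigned != list(range(1, 11)):
            raise ValueError("BQREB factor map must partition items 1..10")
    bqreb = InstrumentSpec(
        name="BQREB",
        column_prefix="BQREB",
        items=tuple(Item(i, 1, 4) for i in range(1, 11)),
        subscales={k: tuple((i, False) for i in v) for k, v in bq.items()},
    )
    return {s.name: s for s in (pansi, apgar, bssa, bqreb)}


def subscale_owner(subscale: str, specs: Mapping[str, InstrumentSpec] | None = None) -> InstrumentSpec:
    """Find the instrument spec that owns a subscale column name."""
    specs = specs or builtin_specs()
    for spec in specs.values():
        if subscale in spec.subscales:
            return spec
    raise KeyError(f"no instrument owns subscale {subscale!r}")


@dataclass
class ResponseMatrix:
    """Respondent x item response matrix.

    ``data`` is indexed by respondent id with one pandas nullable-``Int64``
    column per item (``PANSI_1 ... BQREB_10``); ``pd.NA`` marks missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype("Int64")
        self.data.index.name = "respondent"

    @property
    def respondent_ids(self) -> list:
        return list(self.data.index)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        """Read the CSV dialect: header row, optional ``respondent`` id
        column, one ``<PREFIX>_<item>`` column per item, empty cell = missing."""
        df = pd.read_csv(path)
        if "respondent" in df.columns:
            df = df.set_index("respondent")
        else:
            df.index.name = "respondent"
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)


@dataclass
class ScoreTable:
    """Respondent x subscale integer scores (``pd.NA`` where the respondent
    was excluded listwise for that subscale)."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = self.scores.astype("Int64")
        self.scores.index.name = "respondent"

    @property
    def respondent_ids(self) -> list:
        return list(self.scores.index)

    def pair(self, col1: str, col2: str) -> np.ndarray:
        """Complete-case (n, 2) float array for a score pair."""
        sub = self.scores[[col1, col2]].dropna()
        return sub.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, index_col="respondent"))

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path)


def score_subscale(
    responses: ResponseMatrix, spec: InstrumentSpec, subscale: str
) -> pd.Series:
    """Score one subscale: sum of (reverse-keyed) responses per respondent.

    Respondents missing any subscale item receive ``pd.NA`` (listwise
    exclusion). Returns a nullable-integer Series over all respondents.
    """
    members = spec._members(subscale)
    cols = [spec.column(i) for i, _ in members]
    missing_cols = [c for c in cols if c not in responses.data.columns]
    if missing_cols:
        raise KeyError(f"{spec.name}.{subscale}: response columns absent: {missing_cols}")
    block = responses.data[cols].copy()
    for item_id, rev in members:
        if rev:
            col = spec.column(item_id)
            block[col] = spec.reverse(item_id, block[col])
    complete = block.notna().all(axis=1)
    out = pd.Series(pd.NA, index=block.index, dtype="Int64", name=subscale)
    out[complete] = block[complete].sum(axis=1).astype("Int64")
    if not complete.any():
        warnings.warn(
            f"{spec.name}.{subscale}: every respondent excluded listwise",
            stacklevel=2,
        )
    return out


def score_all(
    responses: ResponseMatrix,
    specs: Mapping[str, InstrumentSpec] | None = None,
) -> ScoreTable:
    """Score all nine subscales into a :class:`ScoreTable` in canonical order."""
    specs = specs or builtin_specs()
    cols = {}
    for spec in specs.values():
        for subscale in spec.subscales:
            cols[subscale] = score_subscale(responses, spec, subscale)
    ordered = [c for c in SUBSCALE_COLUMNS if c in cols]
    ordered += [c for c in cols if c not in SUBSCALE_COLUMNS]
    return ScoreTable(pd.DataFrame({c: cols[c] for c in ordered}))


def classify_apgar(score: int) -> str:
    """Map an APGAR total (0-10) to its family-dysfunction category."""
    if not 0 <= score <= 10:
        raise ValueError(f"APGAR score {score} outside [0, 10]")
    for (lo, hi), label in APGAR_CATEGORIES:
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable: categories cover 0-10")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_responses`; purely descriptive."""

    out_of_range: list[tuple[object, str, int]] = field(default_factory=list)
    missing: list[tuple[object, str]] = field(default_factory=list)
    excluded: dict[str, list] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.out_of_range and not self.missing


def validate_responses(
    responses: ResponseMatrix, spec: InstrumentSpec
) -> ValidationReport:
    """Report out-of-range cells, missing cells, and listwise exclusions for
    one instrument. Never mutates the input."""
    report = ValidationReport()
    df = responses.data
    for it in spec.items:
        col = spec.column(it.item_id)
        if col not in df.columns:
            continue
        vals = df[col]
        isna = vals.isna()
        for rid in df.index[isna]:
            report.missing.append((rid, col))
        bad = ~isna & ((vals < it.min_response) | (vals > it.max_response))
        for rid in df.index[bad]:
            report.out_of_range.append((rid, col, int(vals[rid])))
    for subscale, members in spec.subscales.items():
        cols = [spec.column(i) for i, _ in members if spec.column(i) in df.columns]
        if not cols:
            continue
        incomplete = df[cols].isna().any(axis=1)
        if incomplete.any():
            report.excluded[subscale] = list(df.index[incomplete])
    return report
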