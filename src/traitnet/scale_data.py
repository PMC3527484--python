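"""Score matrices, scale definitions and facet-level aggregation.

The data model mirrors hierarchical questionnaires like the NEO-PI-R:
integer Likert item responses per subject, items grouped into facets,
facets grouped into factors. Loading is strict — missing cells,
out-of-range values and duplicate labels are rejected at the door,
since none of the downstream statistics define behaviour for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class ScaleDataError(ValueError):
    """Raised for malformed score matrices or scale definitions."""


@dataclass(frozen=True)
class ItemScoreMatrix:
    """Subjects x variables matrix of integer Likert responses.

    Parameters
    ----------
    subjects : ordered subject identifiers (row labels).
    variables : ordered variable labels (column labels), unique.
    scores : integer array of shape ``(len(subjects), len(variables))``.
    likert_range : inclusive ``(low, high)`` bounds of the response scale.
    """

    subjects: tuple[str, ...]
    variables: tuple[str, ...]
    scores: np.ndarray
    likert_range: tuple[int, int] = (0, 5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "variables", tuple(str(v) for v in self.variables))
        arr = np.asarray(self.scores)
        if arr.ndim != 2 or arr.shape != (len(self.subjects), len(self.variables)):
            raise ScaleDataError(
                f"score array shape {arr.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variables)} variables"
            )
        if len(self.subjects) < 3:
            raise ScaleDataError("need at least 3 subjects")
        if len(set(self.variables)) != len(self.variables):
            dupes = sorted({v for v in self.variables if self.variables.count(v) > 1})
            raise ScaleDataError(f"duplicate variable labels: {dupes}")
        if len(set(self.subjects)) != len(self.subjects):
            raise ScaleDataError("duplicate subject identifiers")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.isnan(np.asarray(arr, dtype=float)).any():
                raise ScaleDataError("missing cells in score matrix")
            if not np.array_equal(arr, np.asarray(arr, dtype=np.int64)):
                raise ScaleDataError("non-integer scores in item matrix")
            arr = np.asarray(arr, dtype=np.int64)
        lo, hi = self.likert_range
        if arr.size and (arr.min() < lo or arr.max() > hi):
            bad = np.argwhere((arr < lo) | (arr > hi))[0]
            raise ScaleDataError(
                f"score {arr[bad[0], bad[1]]} outside Likert range [{lo}, {hi}] "
                f"at row {self.subjects[bad[0]]!r}, column {self.variables[bad[1]]!r}"
            )
        arr = np.asarray(arr, dtype=np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.subjects), columns=list(self.variables)
        )

    def to_score_matrix(self) -> "ScoreMatrix":
        """Real-valued view, for use where item/facet level is interchangeable."""
        return ScoreMatrix(self.subjects, self.variables, self.scores.astype(float))


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued subjects x variables matrix (facet, factor or cluster scores)."""

    subjects: tuple[str, ...]
    variables: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "variables", tuple(str(v) for v in self.variables))
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.subjects), len(self.variables)):
            raise ScaleDataError(
                f"score array shape {arr.shape} does not match labels"
            )
        if len(set(self.variables)) != len(self.variables):
            raise ScaleDataError("duplicate variable labels")
        if np.isnan(arr).any():
            raise ScaleDataError("missing cells in score matrix")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.subjects), columns=list(self.variables)
        )

    def column(self, label: str) -> np.ndarray:
        return self.scores[:, self.variables.index(label)]


@dataclass(frozen=True)
class ScaleDefinition:
    """Item -> facet -> factor hierarchy.

    ``facet_of`` maps each item to exactly one facet, ``factor_of`` each facet
    to exactly one factor. Iteration orders follow first appearance in
    ``items``, so aggregation output is deterministic.
    """

    items: tuple[str, ...]
    facet_of: Mapping[str, str]
    factor_of: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(str(i) for i in self.items))
        if len(set(self.items)) != len(self.items):
            dupes = sorted({i for i in self.items if self.items.count(i) > 1})
            raise ScaleDataError(f"duplicate item IDs: {dupes}")
        if not self.items:
            raise ScaleDataError("scale definition has no items")
        missing = [i for i in self.items if i not in self.facet_of]
        if missing:
            raise ScaleDataError(f"items with no facet: {missing}")
        orphans = sorted(
            {f for f in self.facet_of.values() if f not in self.factor_of}
        )
        if orphans:
            raise ScaleDataError(f"facets with no factor: {orphans}")
        unused = sorted(set(self.factor_of) - set(self.facet_of.values()))
        if unused:
            raise ScaleDataError(f"facets with zero items: {unused}")

    @property
    def facets(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for item in self.items:
            seen.setdefault(self.facet_of[item], None)
        return tuple(seen)

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for facet in self.facets:
            seen.setdefault(self.factor_of[facet], None)
        return tuple(seen)

    def items_in_facet(self, facet: str) -> tuple[str, ...]:
        return tuple(i for i in self.items if self.facet_of[i] == facet)

    def facets_in_factor(self, factor: str) -> tuple[str, ...]:
        return tuple(f for f in self.facets if self.factor_of[f] == factor)

    def items_in_factor(self, factor: str) -> tuple[str, ...]:
        return tuple(
            i for i in self.items if self.factor_of[self.facet_of[i]] == factor
        )

    def item_factor_map(self) -> dict[str, str]:
        return {i: self.factor_of[self.facet_of[i]] for i in self.items}

    def is_neo_layout(self) -> bool:
        """True for the canonical 240-item layout: 8 items/facet, 6 facets/factor, 5 factors."""
        if len(self.factors) != 5 or len(self.facets) != 30 or len(self.items) != 240:
            return False
        if any(len(self.items_in_facet(f)) != 8 for f in self.facets):
            return False
        return all(len(self.facets_in_factor(f)) == 6 for f in self.factors)


def load_item_scores(
    path: str | Path,
    likert_range: tuple[int, int] = (0, 5),
    delimiter: str | None = None,
) -> ItemScoreMatrix:
    """Read a delimited score file: header of variable labels, first column subject IDs.

    The delimiter is sniffed from the header (comma vs tab) unless given.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ScaleDataError(f"{path}: empty score file")
    if delimiter is None:
        first = text.splitlines()[0]
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ScaleDataError(f"{path}: no variable columns found")
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ScaleDataError(f"{path}: missing cell at row {row!r}, column {col!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ScaleDataError(f"{path}: non-numeric cell ({exc})") from exc
    return ItemScoreMatrix(
        subjects=tuple(str(s) for s in df.index),
        variables=tuple(str(c) for c in df.columns),
        scores=values.to_numpy(),
        likert_range=likert_range,
    )


def save_item_scores(matrix: ItemScoreMatrix | ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix as CSV (round-trips through :func:`load_item_scores`)."""
    df = matrix.to_frame()
    df.index.name = "subject"
    df.to_csv(path)


def load_scale_definition(path: str | Path) -> ScaleDefinition:
    """Read an item/facet/factor map from YAML or CSV.

    CSV needs columns ``item, facet, factor``. YAML is a nested mapping
    ``{factor: {facet: [items...]}}``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        spec = yaml.safe_load(path.read_text())
        if not isinstance(spec, dict):
            raise ScaleDataError(f"{path}: expected a factor->facet->items mapping")
        items: list[str] = []
        facet_of: dict[str, str] = {}
        factor_of: dict[str, str] = {}
        for factor, facets in spec.items():
            for facet, members in facets.items():
                if str(facet) in factor_of:
                    raise ScaleDataError(f"{path}: facet {facet!r} listed twice")
                factor_of[str(facet)] = str(factor)
                for item in members:
                    item = str(item)
                    if item in facet_of:
                        raise ScaleDataError(
                            f"{path}: item {item!r} mapped to two facets"
                        )
                    facet_of[item] = str(facet)
                    items.append(item)
        return ScaleDefinition(tuple(items), facet_of, factor_of)
    df = pd.read_csv(path, dtype=str)
    required = {"item", "facet", "factor"}
    if not required.issubset(df.columns):
        raise ScaleDataError(f"{path}: need columns {sorted(required)}")
    if df["item"].duplicated().any():
        dupes = sorted(df.loc[df["item"].duplicated(), "item"])
        raise ScaleDataError(f"{path}: item mapped to two facets: {dupes}")
    conflicting = df.groupby("facet")["factor"].nunique()
    bad = conflicting[conflicting > 1].index.tolist()
    if bad:
        raise ScaleDataError(f"{path}: facets mapped to two factors: {bad}")
    facet_of = dict(zip(df["item"], df["facet"]))
    factor_of = dict(zip(df["facet"], df["factor"]))
    return ScaleDefinition(tuple(df["item"]), facet_of, factor_of)


def save_scale_definition(scale: ScaleDefinition, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {"item": i, "facet": scale.facet_of[i], "factor": scale.factor_of[scale.facet_of[i]]}
        for i in scale.items
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def aggregate_facet_scores(
    scores: ItemScoreMatrix, scale: ScaleDefinition
) -> ScoreMatrix:
    """Facet score = arithmetic mean of the facet's member items, per subject."""
    missing = [v for v in scores.variables if v not in scale.facet_of]
    if missing:
        raise ScaleDataError(f"items absent from scale definition: {missing}")
    frame = scores.to_frame().astype(float)
    cols = {}
    for facet in scale.facets:
        members = [i for i in scale.items_in_facet(facet) if i in frame.columns]
        if not members:
            raise ScaleDataError(f"facet {facet!r} has no items in the score matrix")
        cols[facet] = frame[members].mean(axis=1).to_numpy()
    return ScoreMatrix(
        subjects=scores.subjects,
        variables=tuple(cols),
        scores=np.column_stack(list(cols.values())),
    )
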