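"""Tidy tabular abstraction over :class:`~tidycells.container.CellContainer`.

One row per cell. The first column is the key column ``.cell``; cell metadata
columns are editable; reduction dim columns are view-only. Verbs materialize
the view, operate on the plain table, and run the result through
:func:`dispatch`, which decides whether the outcome can stay container-backed
(no cell duplication, key column intact, view-only columns untouched) or must
demote to a :class:`PlainTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import options
from .container import KEY_COLUMN, CellContainer, set_cell_meta_column, subset_cells

logger = logging.getLogger("tidycells")


class ColumnClass(Enum):
    KEY = "key"
    EDITABLE = "editable"
    VIEW_ONLY = "view_only"


@dataclass
class DemotionWarning:
    """Structured record of why a verb returned a plain table."""

    verb: str
    rule: str

    def __str__(self) -> str:
        return f"{self.verb}: result demoted to plain table ({self.rule})"


class PlainTable:
    """An ordinary columnar table with no container back end."""

    def __init__(self, df: pd.DataFrame, warnings: list | None = None):
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dup}")
        self.df = df.reset_index(drop=True)
        self.warnings: list = list(warnings or [])

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other) -> bool:
        other_df = other.df if isinstance(other, PlainTable) else other
        return self.df.equals(other_df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PlainTable({len(self.df)} x {len(self.df.columns)})\n{self.df.head(10)}"


class TidyView:
    """Container-backed cell table: key column, editable metadata, view-only dims."""

    def __init__(
        self,
        backend: CellContainer,
        hidden_columns=(),
        groups=(),
        warnings: list | None = None,
    ):
        self.backend = backend
        self.hidden_columns = set(hidden_columns) - {KEY_COLUMN}
        self.groups = tuple(groups)
        self.warnings: list = list(warnings or [])
        visible = set(self.visible_columns)
        bad = [g for g in self.groups if g not in visible]
        if bad:
            raise NameError(f"group columns not visible: {bad}")

    # -- column bookkeeping --------------------------------------------------

    @property
    def all_columns(self) -> list[str]:
        cols = [KEY_COLUMN]
        cols.extend(self.backend.cell_meta.columns)
        for red in self.backend.reductions.values():
            cols.extend(red.labels)
        return cols

    @property
    def visible_columns(self) -> list[str]:
        return [c for c in self.all_columns if c not in self.hidden_columns]

    @property
    def n_cells(self) -> int:
        return self.backend.n_cells

    def classify(self, name: str) -> ColumnClass:
        if name not in self.visible_columns:
            raise NameError(f"unknown or hidden column: {name!r}")
        if name == KEY_COLUMN:
            return ColumnClass.KEY
        if name in self.backend.reduction_labels():
            return ColumnClass.VIEW_ONLY
        return ColumnClass.EDITABLE

    def _replace(self, **kw) -> "TidyView":
        args = dict(
            backend=self.backend,
            hidden_columns=self.hidden_columns,
            groups=self.groups,
            warnings=self.warnings,
        )
        args.update(kw)
        return TidyView(**args)

    def __repr__(self) -> str:  # pragma: no cover
        return display(self)


# -- core operations ---------------------------------------------------------


def as_tidy(container: CellContainer) -> TidyView:
    """Present a container as a tidy view; no data is copied."""
    return TidyView(container)


def _full_frame(view: TidyView) -> pd.DataFrame:
    """All columns (hidden included), in canonical order, RangeIndex."""
    c = view.backend
    data: dict[str, np.ndarray | list] = {
        KEY_COLUMN: np.asarray(c.cell_ids, dtype=object)
    }
    for col in c.cell_meta.columns:
        data[col] = c.cell_meta[col].to_numpy()
    for red in c.reductions.values():
        for j, lab in enumerate(red.labels):
            data[lab] = red.matrix[:, j]
    return pd.DataFrame(data)


def materialize_df(view: TidyView) -> pd.DataFrame:
    """Visible columns as a plain DataFrame (bit-equal to backend values)."""
    df = _full_frame(view)
    return df[[c for c in df.columns if c not in view.hidden_columns]]


def materialize(view: TidyView) -> PlainTable:
    return PlainTable(materialize_df(view))


def classify_column(view: TidyView, name: str) -> ColumnClass:
    return view.classify(name)


def display_header(view: TidyView, flavor: str | None = None) -> list[str]:
    """Two-line header mirroring the abstraction's summary banner."""
    flavor = options.flavor if flavor is None else flavor
    c = view.backend
    line1 = f"# A {flavor}-table abstraction: {c.n_cells} × {len(view.visible_columns)}"
    line2 = (
        f"# Features = {c.n_features} | Active assay={c.active_assay} "
        f"| Assays={', '.join(c.assays)}"
    )
    return [line1, line2]


def display(view: TidyView, n_rows: int = 10) -> str:
    """Plain-text rendering: header, first rows, and a column-class line."""
    lines = display_header(view)
    df = materialize_df(view).head(n_rows)
    classes = {
        ColumnClass.KEY: "<key>",
        ColumnClass.EDITABLE: "<edit>",
        ColumnClass.VIEW_ONLY: "<view>",
    }
    tag = pd.DataFrame(
        [[classes[view.classify(c)] for c in df.columns]], columns=df.columns
    )
    body = pd.concat([tag, df.astype(object)], ignore_index=True)
    lines.append(body.to_string(index=False))
    if view.groups:
        lines.append(f"# Groups: {', '.join(view.groups)}")
    return "\n".join(lines)


def dispatch(
    result: PlainTable | pd.DataFrame,
    origin: CellContainer,
    origin_view: TidyView | None = None,
    verb: str = "verb",
) -> TidyView | PlainTable:
    """Promote a verb's tabular result back to a container-backed view if legal.

    Promotion requires: the key column is present, holds a duplicate-free
    subset of the origin's cell ids, and no view-only column was altered.
    Otherwise the result is returned as a PlainTable carrying one
    :class:`DemotionWarning`.
    """
    df = result.df if isinstance(result, PlainTable) else result
    prior = list(result.warnings) if isinstance(result, PlainTable) else []

    def demote(rule: str) -> PlainTable:
        w = DemotionWarning(verb, rule)
        logger.warning(str(w))
        return PlainTable(df, warnings=prior + [w])

    if KEY_COLUMN not in df.columns:
        return demote("key column excluded")
    cells = df[KEY_COLUMN].tolist()
    if len(set(cells)) != len(cells):
        return demote("cell duplication")
    known = set(origin.cell_ids)
    if not all(c in known for c in cells):
        return demote("key column modified")

    red_labels = origin.reduction_labels()
    backend = subset_cells(origin, cells)
    for col in df.columns:
        if col == KEY_COLUMN:
            continue
        if col in red_labels:
            name, j = red_labels[col]
            expected = backend.reductions[name].matrix[:, j]
            got = df[col].to_numpy()
            if not np.array_equal(np.asarray(got), np.asarray(expected)):
                return demote("view-only column altered")

    for col in df.columns:
        if col == KEY_COLUMN or col in red_labels:
            continue
        backend = set_cell_meta_column(backend, col, df[col].to_numpy())

    hidden = set(origin_view.hidden_columns) if origin_view is not None else set()
    present = set(df.columns)
    for col in [KEY_COLUMN, *backend.cell_meta.columns, *red_labels]:
        if col != KEY_COLUMN and col not in present:
            hidden.add(col)
    groups = ()
    if origin_view is not None:
        groups = tuple(g for g in origin_view.groups if g in present)
    prior_view = list(origin_view.warnings) if origin_view is not None else []
    return TidyView(backend, hidden_columns=hidden, groups=groups, warnings=prior_view)
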