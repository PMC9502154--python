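"""Transcript-level access and nested per-group analysis.

``join_features`` pulls per-cell abundance of selected features into the cell
table — wide (one editable column per feature, still container-backed) or
long (one row per cell/feature pair, a plain table by construction).

``nest``/``map_nested``/``unnest`` split the cell table into per-group
sub-containers held in a table column, apply functions per group, and
reassemble — replacing manual subset/iterate/reintegrate loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .container import (
    KEY_COLUMN,
    CellContainer,
    concat_containers,
    set_cell_meta_column,
    subset_cells,
)
from .errors import DuplicationError, FeatureNotFoundError, GroupKeyError, NameCollisionError
from .view import ColumnClass, PlainTable, TidyView, as_tidy, materialize_df


def _resolve_slot(container: CellContainer, assay: str | None, slot: str | None):
    name = container.active_assay if assay is None else assay
    if name not in container.assays:
        raise NameError(f"unknown assay: {name!r}")
    a = container.assays[name]
    if slot is None:
        slot = "data" if "data" in a.slots else "counts"
    if slot not in a.slots:
        raise NameError(f"assay {name!r} has no slot {slot!r}")
    return name, slot, a


def feature_values(
    container: CellContainer, features, assay: str | None = None, slot: str | None = None
) -> pd.DataFrame:
    """Per-cell values of the given features (cells x features DataFrame)."""
    features = [features] if isinstance(features, str) else list(features)
    name, slot, a = _resolve_slot(container, assay, slot)
    index = {f: i for i, f in enumerate(a.feature_ids)}
    missing = [f for f in features if f not in index]
    if missing:
        raise FeatureNotFoundError(missing)
    rows = [index[f] for f in features]
    block = np.asarray(a.slots[slot][rows, :].todense())  # features x cells
    return pd.DataFrame(block.T, columns=features, index=pd.Index(container.cell_ids))


def join_features(
    view: TidyView,
    features,
    shape: str = "wide",
    assay: str | None = None,
    slot: str | None = None,
):
    """Add transcript abundance to the cell table.

    wide: one new editable column per feature (container-backed view).
    long: plain table with ``.feature`` / ``.abundance`` / ``.assay`` columns,
    one row per cell and feature, cells varying slowest.
    """
    features = [features] if isinstance(features, str) else list(features)
    c = view.backend
    vals = feature_values(c, features, assay=assay, slot=slot)
    assay_name, _, _ = _resolve_slot(c, assay, slot)
    if shape == "wide":
        taken = set(c.cell_meta.columns) | set(c.reduction_labels())
        clash = [f for f in features if f in taken]
        if clash:
            raise NameCollisionError(f"feature columns already exist in the table: {clash}")
        backend = c
        for f in features:
            backend = set_cell_meta_column(backend, f, vals[f].to_numpy())
        return TidyView(backend, hidden_columns=view.hidden_columns,
                        groups=view.groups, warnings=view.warnings)
    if shape == "long":
        df = materialize_df(view)
        rows = df.loc[df.index.repeat(len(features))].reset_index(drop=True)
        rows[".feature"] = features * len(df)
        rows[".abundance"] = vals.to_numpy().ravel()  # cells x features, row-major
        rows[".assay"] = assay_name
        return PlainTable(rows)
    raise ValueError(f"shape must be 'wide' or 'long', got {shape!r}")


@dataclass
class NestedTable:
    """One row per group: key columns (plus mapped results) and sub-containers."""

    keys: pd.DataFrame
    containers: list[CellContainer]
    group_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.group_columns:
            self.group_columns = list(self.keys.columns)
        if len(self.keys) != len(self.containers):
            raise GroupKeyError("one container required per key row")
        if self.keys[self.group_columns].duplicated().any():
            raise GroupKeyError("group key combinations must be unique")

    @property
    def n_groups(self) -> int:
        return len(self.containers)

    def __repr__(self) -> str:  # pragma: no cover
        tab = self.keys.copy()
        tab["data"] = [f"<CellContainer {c.n_cells} cells>" for c in self.containers]
        return f"NestedTable {len(tab)} × {len(tab.columns)}\n{tab.to_string(index=False)}"


def nest(view: TidyView, by) -> NestedTable:
    """Split into per-group sub-containers, first-occurrence group order.

    The nesting columns move out of the sub-containers' metadata and into the
    key table; null keys form their own group.
    """
    by = [by] if isinstance(by, str) else list(by)
    if not by:
        raise GroupKeyError("nest requires at least one key column")
    for c in by:
        if view.classify(c) is not ColumnClass.EDITABLE:
            raise GroupKeyError(f"nest keys must be editable metadata columns, got {c!r}")
    df = materialize_df(view)
    keys = df[by].drop_duplicates().reset_index(drop=True)
    containers = []
    grouped = df.groupby(by, sort=False, dropna=False)
    for _, sub in grouped:
        sub_container = subset_cells(view.backend, sub[KEY_COLUMN].tolist())
        sub_container.cell_meta = sub_container.cell_meta.drop(columns=by)
        containers.append(sub_container)
    return NestedTable(keys, containers)


def map_nested(nested: NestedTable, fn, out_column: str) -> NestedTable:
    """Apply ``fn(container) -> value`` per group; results become a key column."""
    results = []
    for i, c in enumerate(nested.containers):
        try:
            results.append(fn(c))
        except Exception as exc:
            key = nested.keys[nested.group_columns].iloc[i].to_dict()
            exc.add_note(f"while mapping group {key}")
            raise
    keys = nested.keys.copy()
    keys[out_column] = pd.Series(results, dtype=object)
    return NestedTable(keys, list(nested.containers), list(nested.group_columns))


def unnest(nested: NestedTable) -> TidyView:
    """Reassemble a nested table; group keys return as editable metadata."""
    seen: set[str] = set()
    for c in nested.containers:
        ids = set(c.cell_ids)
        if seen & ids:
            raise DuplicationError("nested containers share cell ids")
        seen |= ids
    combined, warns = concat_containers(list(nested.containers), feature_policy="union")
    for col in nested.group_columns:
        values = np.concatenate(
            [
                np.repeat(nested.keys[col].iloc[[i]].to_numpy(), c.n_cells)
                for i, c in enumerate(nested.containers)
            ]
        ) if combined.n_cells else np.array([])
        combined = set_cell_meta_column(combined, col, values)
    view = as_tidy(combined)
    view.warnings.extend(warns)
    return view
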