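"""Grammar-of-data verbs over :class:`~tidycells.view.TidyView`.

Every verb follows the same shape: materialize the view, perform an ordinary
tabular operation, then hand the result to :func:`~tidycells.view.dispatch`,
which keeps it container-backed when legal and demotes it to a
:class:`~tidycells.view.PlainTable` otherwise. Aggregating verbs (``count``,
``summarise``, ``distinct``, ``pull``, ``pivot_longer``) return tables or
arrays by design.

Expressions for ``mutate``/``filter``/``summarise`` are vectorized: either a
string evaluated with :meth:`pandas.DataFrame.eval` (backtick-quote names with
spaces), a callable taking the materialized DataFrame, a scalar, or an
array-like. Row-wise Python callbacks are deliberately unsupported so verb
output can be checked against a dense relational oracle.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .container import KEY_COLUMN, concat_containers
from .errors import (
    JoinKeyError,
    NameCollisionError,
    ParamError,
    PatternError,
    ReadOnlyColumnError,
    SampleSizeError,
    AggregationError,
)
from .view import (
    ColumnClass,
    DemotionWarning,
    PlainTable,
    TidyView,
    dispatch,
    materialize_df,
)

__all__ = [
    "mutate", "rename", "select", "filter", "slice", "arrange", "sample_cells",
    "group_by", "ungroup", "count", "summarise", "distinct", "pull",
    "join_metadata", "bind_rows", "separate", "unite", "extract_regex",
    "pivot_longer",
]


# -- expression machinery ----------------------------------------------------


def _eval_expr(df: pd.DataFrame, expr):
    """Evaluate one vectorized expression against a DataFrame."""
    try:
        if callable(expr):
            return expr(df)
        if isinstance(expr, str):
            return df.eval(expr, engine="python")
    except KeyError as exc:
        raise NameError(f"unknown column referenced: {exc}") from exc
    return expr


def _eval_maybe_grouped(df: pd.DataFrame, expr, groups):
    """Evaluate per group (broadcasting scalars) when grouped, else globally."""
    if not groups:
        out = _eval_expr(df, expr)
        if np.ndim(out) == 0:
            out = pd.Series([out] * len(df), index=df.index)
        return pd.Series(np.asarray(out), index=df.index)
    result = pd.Series(index=df.index, dtype=object)
    for _, sub in df.groupby(list(groups), sort=False, dropna=False):
        val = _eval_expr(sub, expr)
        if np.ndim(val) == 0:
            result.loc[sub.index] = val
        else:
            result.loc[sub.index] = np.asarray(val)
    return pd.Series(result.to_numpy().tolist(), index=df.index)


def _check_writable(view: TidyView, name: str, verb: str):
    if name in view.backend.reduction_labels():
        raise ReadOnlyColumnError(f"{verb}: {name!r} is view-only (reduction dim)")


# -- column-manipulating verbs -----------------------------------------------


def mutate(view: TidyView, assignments: dict | None = None, **kw):
    """Add or overwrite columns. Writing the key column demotes; view-only errors."""
    assigns = {**(assignments or {}), **kw}
    for name in assigns:
        _check_writable(view, name, "mutate")
    df = materialize_df(view).copy()
    for name, expr in assigns.items():
        df[name] = _eval_maybe_grouped(df, expr, view.groups).to_numpy()
    return dispatch(df, view.backend, view, verb="mutate")


def rename(view: TidyView, mapping: dict):
    """Rename columns (old -> new). Renaming the key or a view-only column demotes."""
    visible = view.visible_columns
    for old in mapping:
        if old not in visible:
            raise NameError(f"unknown column: {old!r}")
    taken = set(visible) - set(mapping)
    for new in mapping.values():
        if new in taken or new in view.backend.reduction_labels():
            raise NameCollisionError(f"column {new!r} already exists")
    df = materialize_df(view).rename(columns=mapping)
    return dispatch(df, view.backend, view, verb="rename")


def select(view: TidyView, keep: list[str]):
    """Keep only the listed columns; dropping the key column demotes."""
    visible = view.visible_columns
    unknown = [c for c in keep if c not in visible]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    df = materialize_df(view)[list(keep)]
    return dispatch(df, view.backend, view, verb="select")


def filter(view: TidyView, predicate) -> TidyView:  # noqa: A001 - dplyr naming
    """Subset cells by a row-wise boolean predicate; original order kept."""
    df = materialize_df(view)
    mask = _eval_maybe_grouped(df, predicate, view.groups)
    mask = np.asarray(mask.tolist(), dtype=bool)
    return dispatch(df[mask], view.backend, view, verb="filter")


def slice(view: TidyView, positions):  # noqa: A001 - dplyr naming
    """Pick rows by 1-based position, in the given order; repeats demote."""
    n = view.n_cells
    positions = [int(p) for p in positions]
    bad = [p for p in positions if p < 1 or p > n]
    if bad:
        raise IndexError(f"slice positions out of range 1..{n}: {bad}")
    df = materialize_df(view).iloc[[p - 1 for p in positions]]
    return dispatch(df, view.backend, view, verb="slice")


def arrange(view: TidyView, by, descending=False) -> TidyView:
    """Stable sort of cells by one or more columns."""
    by = [by] if isinstance(by, str) else list(by)
    if isinstance(descending, bool):
        descending = [descending] * len(by)
    visible = view.visible_columns
    unknown = [c for c in by if c not in visible]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    df = materialize_df(view).sort_values(
        by=by, ascending=[not d for d in descending], kind="stable"
    )
    return dispatch(df, view.backend, view, verb="arrange")


def sample_cells(
    view: TidyView,
    n: int | None = None,
    frac: float | None = None,
    replace: bool = False,
    seed: int | None = None,
):
    """Random cell sample; per group when grouped. With replacement demotes."""
    if (n is None) == (frac is None):
        raise ParamError("exactly one of n/frac must be given")
    if frac is not None and not (0 < frac <= 1):
        raise ParamError(f"frac must be in (0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    df = materialize_df(view)

    def take(sub: pd.DataFrame) -> np.ndarray:
        k = n if n is not None else int(round(frac * len(sub)))
        if not replace and k > len(sub):
            raise SampleSizeError(f"cannot take {k} of {len(sub)} cells without replacement")
        return rng.choice(sub.index.to_numpy(), size=k, replace=replace)

    if view.groups:
        picked = np.concatenate(
            [take(sub) for _, sub in df.groupby(list(view.groups), sort=False, dropna=False)]
        )
    else:
        picked = take(df)
    result = df.loc[picked]
    if replace:  # duplication possible by construction: always a plain table
        w = DemotionWarning("sample_cells", "sampling with replacement may duplicate cells")
        return PlainTable(result, warnings=[w])
    return dispatch(result, view.backend, view, verb="sample_cells")


# -- grouping and aggregation ------------------------------------------------


def group_by(view: TidyView, *columns) -> TidyView:
    """Set grouping columns (affects sampling, counting, mutate aggregates)."""
    cols = [c for arg in columns for c in ([arg] if isinstance(arg, str) else arg)]
    visible = view.visible_columns
    unknown = [c for c in cols if c not in visible]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    return view._replace(groups=tuple(cols))


def ungroup(view: TidyView) -> TidyView:
    return view._replace(groups=())


def count(view: TidyView, by=None, name: str = "n", add: bool = False):
    """Group sizes: a key/count table, or (``add=True``) a broadcast column."""
    by = list(view.groups) if by is None else ([by] if isinstance(by, str) else list(by))
    visible = view.visible_columns
    unknown = [c for c in by if c not in visible]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    df = materialize_df(view)
    if add:
        if name in visible:
            raise NameCollisionError(f"count column {name!r} already exists")
        out = df.copy()
        if by:
            out[name] = df.groupby(by, sort=False, dropna=False)[KEY_COLUMN].transform("size")
        else:
            out[name] = len(df)
        return dispatch(out, view.backend, view, verb="count")
    if not by:
        return PlainTable(pd.DataFrame({name: [len(df)]}))
    tab = df.groupby(by, sort=False, dropna=False).size().reset_index(name=name)
    return PlainTable(tab)


def summarise(view: TidyView, aggregations: dict | None = None, **kw) -> PlainTable:
    """Reduce each group to one row; always a plain table."""
    aggs = {**(aggregations or {}), **kw}
    df = materialize_df(view)

    def reduce_one(sub: pd.DataFrame) -> dict:
        row = {}
        for name, expr in aggs.items():
            val = _eval_expr(sub, expr)
            if np.ndim(val) != 0:
                val = np.asarray(val)
                if val.size != 1:
                    raise AggregationError(f"aggregation {name!r} returned {val.size} values")
                val = val.item()
            row[name] = val
        return row

    if not view.groups:
        if len(df) == 0 and aggs:
            return PlainTable(pd.DataFrame(columns=list(aggs)))
        return PlainTable(pd.DataFrame([reduce_one(df)]))
    rows = []
    for key, sub in df.groupby(list(view.groups), sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(view.groups, key)), **reduce_one(sub)})
    cols = [*view.groups, *aggs]
    return PlainTable(pd.DataFrame(rows, columns=cols))


def distinct(view: TidyView, columns=None) -> PlainTable:
    """Unique combinations of the given columns, first-occurrence order."""
    cols = view.visible_columns if columns is None else (
        [columns] if isinstance(columns, str) else list(columns)
    )
    unknown = [c for c in cols if c not in view.visible_columns]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    return PlainTable(materialize_df(view)[cols].drop_duplicates())


def pull(view: TidyView, column: str) -> np.ndarray:
    """One column as a bare array, in row order."""
    if column not in view.visible_columns:
        raise NameError(f"unknown column: {column!r}")
    return materialize_df(view)[column].to_numpy()


# -- joins and concatenation -------------------------------------------------


def join_metadata(view: TidyView, other, by, mode: str = "left"):
    """Relational join against an ordinary table; dispatch rules apply."""
    by = [by] if isinstance(by, str) else list(by)
    if not by:
        raise JoinKeyError("join requires at least one key column")
    if mode not in ("left", "inner", "right"):
        raise ParamError(f"mode must be left|inner|right, got {mode!r}")
    other_df = other.df if isinstance(other, PlainTable) else pd.DataFrame(other)
    red = set(view.backend.reduction_labels())
    clash = [c for c in other_df.columns if c in red]
    if clash:
        raise NameCollisionError(f"join table carries view-only column names: {clash}")
    df = materialize_df(view)
    missing = [c for c in by if c not in df.columns or c not in other_df.columns]
    if missing:
        raise NameError(f"join columns absent from one side: {missing}")
    merged = df.merge(other_df, on=by, how=mode)
    if merged[KEY_COLUMN].isna().any():
        w = DemotionWarning("join_metadata", "rows without a backing cell")
        return PlainTable(merged, warnings=[w])
    return dispatch(merged, view.backend, view, verb="join_metadata")


def bind_rows(
    a: TidyView,
    b: TidyView,
    feature_policy: str = "union",
    make_unique: bool = False,
) -> TidyView:
    """Concatenate two datasets cell-wise (disjoint cell ids required)."""
    combined, warns = concat_containers(
        [a.backend, b.backend], feature_policy=feature_policy, make_unique=make_unique
    )
    view = TidyView(combined, warnings=[*a.warnings, *b.warnings, *warns])
    hidden = (a.hidden_columns | b.hidden_columns) & set(view.all_columns)
    return view._replace(hidden_columns=hidden)


# -- string reshaping --------------------------------------------------------


def _editable_only(view: TidyView, columns, verb: str):
    for c in columns:
        if view.classify(c) is not ColumnClass.EDITABLE:
            raise ReadOnlyColumnError(f"{verb}: {c!r} is not an editable metadata column")


def separate(view: TidyView, column: str, into: list[str], sep: str = "_"):
    """Split one string column into several at a separator."""
    _editable_only(view, [column], "separate")
    df = materialize_df(view)
    taken = set(df.columns) - {column}
    clash = [c for c in into if c in taken or c in view.backend.reduction_labels()]
    if clash:
        raise NameCollisionError(f"separate targets already exist: {clash}")
    parts = df[column].astype("string").str.split(sep, expand=True)
    parts = parts.reindex(columns=range(len(into)))
    pos = list(df.columns).index(column)
    out = df.drop(columns=[column])
    for offset, name in enumerate(into):
        out.insert(pos + offset, name, parts[offset].to_numpy())
    return dispatch(out, view.backend, view, verb="separate")


def unite(view: TidyView, new: str, columns: list[str], sep: str = "_"):
    """Concatenate several columns into one string column."""
    _editable_only(view, columns, "unite")
    df = materialize_df(view)
    if (new in set(df.columns) - set(columns)) or new in view.backend.reduction_labels():
        raise NameCollisionError(f"column {new!r} already exists")
    joined = df[columns].astype(str).agg(sep.join, axis=1)
    pos = list(df.columns).index(columns[0])
    out = df.drop(columns=columns)
    out.insert(min(pos, len(out.columns)), new, joined.to_numpy())
    return dispatch(out, view.backend, view, verb="unite")


def extract_regex(view: TidyView, column: str, into: list[str], pattern: str):
    """Regex capture groups from one column into new columns."""
    _editable_only(view, [column], "extract_regex")
    compiled = re.compile(pattern)
    if compiled.groups == 0:
        raise PatternError(f"pattern {pattern!r} has no capture groups")
    if compiled.groups != len(into):
        raise PatternError(
            f"pattern has {compiled.groups} groups for {len(into)} target columns"
        )
    df = materialize_df(view)
    taken = set(df.columns) - {column}
    clash = [c for c in into if c in taken or c in view.backend.reduction_labels()]
    if clash:
        raise NameCollisionError(f"extract targets already exist: {clash}")
    caught = df[column].astype("string").str.extract(compiled)
    pos = list(df.columns).index(column)
    out = df.drop(columns=[column])
    for offset, name in enumerate(into):
        out.insert(pos + offset, name, caught.iloc[:, offset].to_numpy())
    return dispatch(out, view.backend, view, verb="extract_regex")


def pivot_longer(
    view: TidyView,
    columns: list[str],
    names_to: str = "name",
    values_to: str = "value",
) -> PlainTable:
    """Lengthen: one row per (cell, pivoted column). Always a plain table."""
    visible = view.visible_columns
    unknown = [c for c in columns if c not in visible]
    if unknown:
        raise NameError(f"unknown columns: {unknown}")
    df = materialize_df(view)
    id_vars = [c for c in visible if c not in columns]
    if names_to in id_vars or values_to in id_vars:
        raise NameCollisionError(
            f"{names_to!r}/{values_to!r} collide with a remaining column"
        )
    # placeholder names dodge pandas' melt restriction when a pivoted column
    # happens to be called values_to
    long = pd.melt(
        df, id_vars=id_vars, value_vars=list(columns),
        var_name="__names__", value_name="__values__",
    ).rename(columns={"__names__": names_to, "__values__": values_to})
    return PlainTable(long)
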