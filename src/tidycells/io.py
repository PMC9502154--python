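"""Readers/writers: 10x-style MatrixMarket triplet directories and CSV tables.

A dataset directory holds ``matrix.mtx`` (features x cells, coordinate
integer), ``features.tsv`` (id, optionally name and type), ``barcodes.tsv``
(one cell id per line), optional ``cell_meta.csv`` (first column ``.cell``)
and optional ``reductions/<name>.csv``.
"""

from __future__ import annotations

import os
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .container import KEY_COLUMN, CellContainer, add_reduction, new_container
from .errors import FormatError
from .view import PlainTable


def read_table_csv(path) -> PlainTable:
    """RFC-4180-ish CSV with a header row; empty fields are nulls."""
    try:
        df = pd.read_csv(path, header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    return PlainTable(df)


def write_table_csv(table, path) -> None:
    df = table.df if isinstance(table, PlainTable) else pd.DataFrame(table)
    df.to_csv(path, index=False)


def _read_ids(path, what: str, max_cols: int | None = None) -> tuple[list[str], pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return [], pd.DataFrame()
    if max_cols is not None and df.shape[1] > max_cols:
        raise FormatError(f"{what} file has {df.shape[1]} columns (max {max_cols})")
    return df[0].tolist(), df


def read_mtx_dir(path) -> CellContainer:
    """Load a triplet directory into a container (counts slot only)."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FormatError(f"missing {mtx}")
    with open(mtx) as fh:
        header = fh.readline()
    matrix = scipy.io.mmread(mtx)
    data = np.asarray(matrix.tocoo().data)
    if "integer" not in header and data.size and np.any(data != np.round(data)):
        raise FormatError(f"{mtx} holds non-integer values")
    counts = sp.csc_matrix(matrix).astype(np.int64)

    feature_ids, fdf = _read_ids(path / "features.tsv", "features", max_cols=3)
    barcodes, _ = _read_ids(path / "barcodes.tsv", "barcodes")
    if counts.shape[0] != len(feature_ids):
        raise FormatError(
            f"matrix has {counts.shape[0]} rows but features.tsv lists {len(feature_ids)}"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {counts.shape[1]} columns but barcodes.tsv lists {len(barcodes)}"
        )

    container = new_container(counts, feature_ids, barcodes)
    if fdf.shape[1] > 1:
        fmeta = fdf.iloc[:, 1:].copy()
        fmeta.columns = ["name", "type"][: fmeta.shape[1]]
        fmeta.index = pd.Index(feature_ids, name="feature")
        container.feature_meta = fmeta

    meta_path = path / "cell_meta.csv"
    if meta_path.exists():
        meta = read_table_csv(meta_path).df
        if KEY_COLUMN not in meta.columns:
            raise FormatError(f"{meta_path} must carry a {KEY_COLUMN!r} column")
        meta = meta.set_index(KEY_COLUMN)
        missing = [b for b in barcodes if b not in meta.index]
        if missing:
            raise FormatError(f"{meta_path} lacks rows for barcodes: {missing[:5]}")
        container.cell_meta = meta.loc[barcodes].set_axis(
            pd.Index(barcodes, name=KEY_COLUMN)
        )

    red_dir = path / "reductions"
    if red_dir.is_dir():
        for f in sorted(red_dir.glob("*.csv")):
            tab = read_table_csv(f).df
            if KEY_COLUMN not in tab.columns:
                raise FormatError(f"{f} must carry a {KEY_COLUMN!r} column")
            tab = tab.set_index(KEY_COLUMN).loc[barcodes]
            container = add_reduction(
                container, f.stem, tab.to_numpy(dtype=float), dim_labels=list(tab.columns)
            )
    return container


def write_mtx_dir(container: CellContainer, path, overwrite: bool = False) -> None:
    """Write counts + ids (+ metadata, reductions) as plain-text triplet files."""
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        if path.is_dir():
            shutil.rmtree(path)
        else:
            os.remove(path)
    path.mkdir(parents=True)

    assay = container.assay()
    counts = sp.csc_matrix(assay.slots["counts"]).astype(np.int64)
    scipy.io.mmwrite(path / "matrix.mtx", counts, field="integer")

    with open(path / "features.tsv", "w") as fh:
        for fid in assay.feature_ids:
            fh.write(f"{fid}\n")
    with open(path / "barcodes.tsv", "w") as fh:
        for cid in container.cell_ids:
            fh.write(f"{cid}\n")

    if len(container.cell_meta.columns):
        meta = container.cell_meta.reset_index()
        meta.to_csv(path / "cell_meta.csv", index=False)

    if container.reductions:
        red_dir = path / "reductions"
        red_dir.mkdir()
        for name, red in container.reductions.items():
            tab = pd.DataFrame(red.matrix, columns=red.labels)
            tab.insert(0, KEY_COLUMN, container.cell_ids)
            tab.to_csv(red_dir / f"{name}.csv", index=False)
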