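"""Hierarchical single-cell data container (the machine-facing back end).

Matrices are stored features x cells, matching 10x triplet files, so I/O
round trips are bit-exact. The cell-major orientation lives entirely in the
tidy view layer. Containers are value-semantic: no operation in this module
mutates its input; anything "modified" is a new container sharing unmodified
sparse blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import options
from .errors import (
    DuplicationError,
    IdentifierError,
    NameCollisionError,
    ParamError,
    ReservedColumnError,
    ShapeError,
)

logger = logging.getLogger("tidycells")

KEY_COLUMN = ".cell"

#: slot names allowed inside an assay
VALID_SLOTS = ("counts", "data")


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise IdentifierError(f"duplicate {what} ids: {sorted(set(map(str, dups)))}")
    return ids


@dataclass
class Assay:
    """A named block of features x cells matrices ("counts" raw, "data" normalized)."""

    name: str
    feature_ids: list[str]
    slots: dict[str, sp.spmatrix] = field(default_factory=dict)

    def __post_init__(self):
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        for slot, m in self.slots.items():
            if slot not in VALID_SLOTS:
                raise NameCollisionError(f"unknown slot {slot!r}; allowed: {VALID_SLOTS}")
            if m.shape[0] != len(self.feature_ids):
                raise ShapeError(
                    f"slot {slot!r} has {m.shape[0]} rows for {len(self.feature_ids)} features"
                )
        if "counts" in self.slots:
            c = self.slots["counts"]
            data = c.tocoo().data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ShapeError("'counts' slot must hold nonnegative integers")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def copy(self) -> "Assay":
        return Assay(self.name, list(self.feature_ids), dict(self.slots))


@dataclass
class Reduction:
    """Per-cell embedding: matrix of shape (n_cells, n_dims) plus dim labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ShapeError("reduction matrix must be 2-D (cells x dims)")
        self.labels = _check_unique(self.labels, "dim label")
        if len(self.labels) != self.matrix.shape[1]:
            raise ShapeError("number of dim labels must equal reduction width")

    def copy(self) -> "Reduction":
        return Reduction(self.matrix.copy(), list(self.labels))


class CellContainer:
    """Assays + cell/feature metadata + reductions, keyed by ordered unique cell ids."""

    def __init__(
        self,
        cell_ids,
        assays: dict[str, Assay],
        active_assay: str,
        cell_meta: pd.DataFrame | None = None,
        feature_meta: pd.DataFrame | None = None,
        reductions: dict[str, Reduction] | None = None,
    ):
        self.cell_ids = _check_unique(cell_ids, "cell")
        self.assays = dict(assays)
        if active_assay not in self.assays:
            raise IdentifierError(f"active assay {active_assay!r} not among {list(self.assays)}")
        self.active_assay = active_assay
        n = len(self.cell_ids)
        for a in self.assays.values():
            for slot, m in a.slots.items():
                if m.shape[1] != n:
                    raise ShapeError(
                        f"assay {a.name!r} slot {slot!r} has {m.shape[1]} columns for {n} cells"
                    )
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name=KEY_COLUMN))
        else:
            cell_meta = cell_meta.copy()
            if len(cell_meta) != n:
                raise ShapeError(f"cell_meta has {len(cell_meta)} rows for {n} cells")
            cell_meta.index = pd.Index(self.cell_ids, name=KEY_COLUMN)
        if KEY_COLUMN in cell_meta.columns:
            raise ReservedColumnError(f"{KEY_COLUMN!r} may not be a metadata column")
        self.cell_meta = cell_meta
        self.feature_meta = (
            pd.DataFrame() if feature_meta is None else feature_meta.copy()
        )
        self.reductions: dict[str, Reduction] = dict(reductions or {})
        for name, red in self.reductions.items():
            if red.matrix.shape[0] != n:
                raise ShapeError(f"reduction {name!r} has {red.matrix.shape[0]} rows for {n} cells")

    # -- basic introspection -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        """Feature count of the active assay."""
        return self.assays[self.active_assay].n_features

    def assay(self, name: str | None = None) -> Assay:
        return self.assays[self.active_assay if name is None else name]

    def reduction_labels(self) -> dict[str, tuple[str, int]]:
        """Map each dim label to its (reduction name, 0-based dim index)."""
        out: dict[str, tuple[str, int]] = {}
        for name, red in self.reductions.items():
            for j, lab in enumerate(red.labels):
                out[lab] = (name, j)
        return out

    def copy(self) -> "CellContainer":
        return CellContainer(
            list(self.cell_ids),
            {k: v.copy() for k, v in self.assays.items()},
            self.active_assay,
            self.cell_meta,
            self.feature_meta,
            {k: v.copy() for k, v in self.reductions.items()},
        )

    def equals(self, other: "CellContainer") -> bool:
        """Exact equality of ids, slots, metadata and reductions (order-sensitive)."""
        if not isinstance(other, CellContainer):
            return False
        if self.cell_ids != other.cell_ids or self.active_assay != other.active_assay:
            return False
        if set(self.assays) != set(other.assays):
            return False
        for name, a in self.assays.items():
            b = other.assays[name]
            if a.feature_ids != b.feature_ids or set(a.slots) != set(b.slots):
                return False
            for slot, m in a.slots.items():
                n = b.slots[slot]
                if m.shape != n.shape or (m != n).nnz != 0:
                    return False
        if not self.cell_meta.equals(other.cell_meta):
            return False
        if set(self.reductions) != set(other.reductions):
            return False
        for name, r in self.reductions.items():
            s = other.reductions[name]
            if r.labels != s.labels or not np.array_equal(r.matrix, s.matrix):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CellContainer({self.n_cells} cells, {self.n_features} features, "
            f"assays={list(self.assays)}, reductions={list(self.reductions)})"
        )


# -- constructors and primitive operations ----------------------------------


def new_container(
    counts: sp.spmatrix,
    feature_ids,
    cell_ids,
    cell_meta: pd.DataFrame | None = None,
    assay_name: str = "RNA",
) -> CellContainer:
    """Build a container around one counts matrix (features x cells)."""
    counts = sp.csc_matrix(counts)
    feature_ids = _check_unique(feature_ids, "feature")
    cell_ids = _check_unique(cell_ids, "cell")
    if counts.shape != (len(feature_ids), len(cell_ids)):
        raise ShapeError(
            f"counts shape {counts.shape} != ({len(feature_ids)}, {len(cell_ids)})"
        )
    assay = Assay(assay_name, feature_ids, {"counts": counts})
    return CellContainer(cell_ids, {assay_name: assay}, assay_name, cell_meta)


def subset_cells(container: CellContainer, keep) -> CellContainer:
    """Restrict all cell-indexed structures to ``keep``, in ``keep`` order."""
    keep = list(keep)
    if len(set(keep)) != len(keep):
        raise DuplicationError("duplicated cell ids in subset; containers forbid duplication")
    pos = {c: i for i, c in enumerate(container.cell_ids)}
    unknown = [c for c in keep if c not in pos]
    if unknown:
        raise IdentifierError(f"unknown cell ids: {unknown[:5]}")
    idx = np.array([pos[c] for c in keep], dtype=int)

    assays = {}
    for name, a in container.assays.items():
        slots = {slot: sp.csc_matrix(m)[:, idx] for slot, m in a.slots.items()}
        assays[name] = Assay(name, list(a.feature_ids), slots)
    reductions = {
        name: Reduction(r.matrix[idx], list(r.labels))
        for name, r in container.reductions.items()
    }
    cell_meta = container.cell_meta.iloc[idx]
    return CellContainer(
        keep, assays, container.active_assay, cell_meta, container.feature_meta, reductions
    )


def set_cell_meta_column(container: CellContainer, name: str, values) -> CellContainer:
    """Return a container with metadata column ``name`` written/overwritten."""
    if name == KEY_COLUMN:
        raise ReservedColumnError(f"{KEY_COLUMN!r} is the key column and cannot be written")
    if name in container.reduction_labels():
        raise ReservedColumnError(f"{name!r} is a reduction dim label (view-only)")
    if np.ndim(values) == 0:
        values = np.full(container.n_cells, values)
    arr = values.to_numpy() if isinstance(values, pd.Series) else np.asarray(values)
    if len(arr) != container.n_cells:
        raise ShapeError(f"{len(arr)} values for {container.n_cells} cells")
    meta = container.cell_meta.copy()
    meta[name] = arr
    return CellContainer(
        list(container.cell_ids),
        container.assays,
        container.active_assay,
        meta,
        container.feature_meta,
        container.reductions,
    )


def default_dim_labels(name: str, d: int, separator: str | None = None) -> list[str]:
    sep = options.reduction_separator if separator is None else separator
    return [f"{name.upper()}{sep}{j + 1}" for j in range(d)]


def add_reduction(
    container: CellContainer,
    name: str,
    embedding,
    dim_labels=None,
    separator: str | None = None,
) -> CellContainer:
    """Attach a cells x d embedding; its dims surface as view-only columns."""
    embedding = np.asarray(embedding)
    if embedding.ndim != 2 or embedding.shape[0] != container.n_cells:
        raise ShapeError(
            f"embedding shape {embedding.shape} does not match {container.n_cells} cells"
        )
    if dim_labels is None:
        dim_labels = default_dim_labels(name, embedding.shape[1], separator)
    taken = set(container.cell_meta.columns) | set(container.reduction_labels())
    clash = [lab for lab in dim_labels if lab in taken]
    if clash:
        raise NameCollisionError(f"dim labels already in use: {clash}")
    reductions = dict(container.reductions)
    reductions[name] = Reduction(embedding.copy(), list(dim_labels))
    return CellContainer(
        list(container.cell_ids),
        container.assays,
        container.active_assay,
        container.cell_meta,
        container.feature_meta,
        reductions,
    )


def set_slot(container: CellContainer, matrix: sp.spmatrix, slot: str, assay: str | None = None):
    """Return a container with ``slot`` of ``assay`` replaced by ``matrix``."""
    name = container.active_assay if assay is None else assay
    a = container.assays[name]
    slots = dict(a.slots)
    slots[slot] = sp.csc_matrix(matrix)
    assays = dict(container.assays)
    assays[name] = Assay(name, list(a.feature_ids), slots)
    return CellContainer(
        list(container.cell_ids),
        assays,
        container.active_assay,
        container.cell_meta,
        container.feature_meta,
        container.reductions,
    )


# -- concatenation ----------------------------------------------------------


def concat_containers(
    containers: list[CellContainer],
    feature_policy: str = "union",
    make_unique: bool = False,
) -> tuple[CellContainer, list[str]]:
    """Stack containers cell-wise; returns (container, warning messages).

    Counts are combined over the union (zero-fill) or intersection of feature
    ids. The "data" slot is never mergeable (normalization is per-dataset) and
    is dropped with a warning. Reductions survive only when present in every
    input with identical dim labels. Assays absent from any input are dropped.
    """
    if feature_policy not in ("union", "intersect"):
        raise ParamError(f"feature_policy must be union|intersect, got {feature_policy!r}")
    warnings: list[str] = []
    all_ids: list[str] = []
    seen: set[str] = set()
    overlap = False
    for c in containers:
        if seen.intersection(c.cell_ids):
            overlap = True
        seen.update(c.cell_ids)
    if overlap and not make_unique:
        raise DuplicationError(
            "overlapping cell ids between datasets; pass make_unique=True to suffix them"
        )
    id_lists = []
    for k, c in enumerate(containers, start=1):
        ids = [f"{i}_{k}" for i in c.cell_ids] if make_unique else list(c.cell_ids)
        id_lists.append(ids)
        all_ids.extend(ids)

    assay_names = [n for n in containers[0].assays if all(n in c.assays for c in containers)]
    dropped_assays = {n for c in containers for n in c.assays} - set(assay_names)
    if dropped_assays:
        warnings.append(f"assays dropped (not present in all inputs): {sorted(dropped_assays)}")

    assays: dict[str, Assay] = {}
    for name in assay_names:
        per = [c.assays[name] for c in containers]
        if any("data" in a.slots for a in per):
            warnings.append(f"'data' slot of assay {name!r} dropped: normalization is not mergeable")
        if feature_policy == "union":
            feats: list[str] = []
            fseen: set[str] = set()
            for a in per:
                for f in a.feature_ids:
                    if f not in fseen:
                        feats.append(f)
                        fseen.add(f)
        else:
            keep = set(per[0].feature_ids)
            for a in per[1:]:
                keep &= set(a.feature_ids)
            feats = [f for f in per[0].feature_ids if f in keep]
        findex = {f: i for i, f in enumerate(feats)}
        blocks = []
        for a in per:
            if "counts" not in a.slots:
                blocks.append(sp.csc_matrix((len(feats), containers[len(blocks)].n_cells)))
                continue
            coo = a.slots["counts"].tocoo()
            rowmap = np.array([findex.get(f, -1) for f in a.feature_ids], dtype=int)
            m = rowmap[coo.row] >= 0
            blocks.append(
                sp.coo_matrix(
                    (coo.data[m], (rowmap[coo.row][m], coo.col[m])),
                    shape=(len(feats), a.slots["counts"].shape[1]),
                )
            )
        counts = sp.hstack(blocks, format="csc") if blocks else sp.csc_matrix((len(feats), 0))
        assays[name] = Assay(name, feats, {"counts": counts.astype(per[0].slots["counts"].dtype)})

    metas = []
    for c, ids in zip(containers, id_lists):
        m = c.cell_meta.copy()
        m.index = pd.Index(ids, name=KEY_COLUMN)
        metas.append(m)
    cell_meta = pd.concat(metas, axis=0, sort=False)

    reductions: dict[str, Reduction] = {}
    red_names = {n for c in containers for n in c.reductions}
    for name in sorted(red_names):
        per = [c.reductions.get(name) for c in containers]
        if any(r is None for r in per) or len({tuple(r.labels) for r in per}) != 1:
            warnings.append(f"reduction {name!r} dropped: not shared with identical dim labels")
            continue
        reductions[name] = Reduction(np.vstack([r.matrix for r in per]), list(per[0].labels))

    fmetas = [c.feature_meta for c in containers if len(c.feature_meta)]
    feature_meta = None
    if fmetas:
        feature_meta = fmetas[0]
        for extra in fmetas[1:]:
            feature_meta = feature_meta.combine_first(extra)

    active = containers[0].active_assay
    if active not in assays:
        active = next(iter(assays))
    out = CellContainer(all_ids, assays, active, cell_meta, feature_meta, reductions)
    for w in warnings:
        logger.warning(w)
    return out, warnings
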