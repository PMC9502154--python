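"""QC metrics, normalization, signature scoring, variable features, a linear
embedding and polygon gating.

The signature score is the case-study primitive: per cell, the min-max
rescaled sum of positive-marker abundance minus the rescaled sum of
negative-marker abundance, so with ``to=(0, 1)`` scores live in [-1, 1] and
are invariant to positive affine transforms of the raw sums.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .config import options
from .container import CellContainer, add_reduction, set_cell_meta_column, set_slot
from .errors import EmptyInputError, FeatureNotFoundError, PolygonError, ShapeError
from .features import feature_values
from .view import TidyView, as_tidy, materialize_df


def _counts(container: CellContainer) -> sp.csc_matrix:
    return sp.csc_matrix(container.assay().slots["counts"])


def _rewrap(view: TidyView, backend: CellContainer) -> TidyView:
    return TidyView(backend, hidden_columns=view.hidden_columns,
                    groups=view.groups, warnings=view.warnings)


# -- QC and normalization ----------------------------------------------------


def compute_qc(view: TidyView, mito_pattern: str = "MT-") -> TidyView:
    """Add total_count, n_detected and mito_fraction metadata columns.

    mito_fraction is the share of counts from features whose id starts with
    ``mito_pattern``; zero-total cells get 0.
    """
    c = view.backend
    counts = _counts(c)
    total = np.asarray(counts.sum(axis=0)).ravel()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_rows = [
        i for i, f in enumerate(c.assay().feature_ids) if str(f).startswith(mito_pattern)
    ]
    if mito_rows:
        mito = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito = np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    backend = set_cell_meta_column(c, "total_count", total)
    backend = set_cell_meta_column(backend, "n_detected", detected)
    backend = set_cell_meta_column(backend, "mito_fraction", frac)
    return _rewrap(view, backend)


def log_normalize(view: TidyView, scale_total: float | None = None) -> TidyView:
    """Write the "data" slot: log1p(count * scale_total / cell_total).

    Zero-total cells stay all-zero; the sparsity pattern is preserved.
    """
    scale_total = options.scale_total if scale_total is None else scale_total
    c = view.backend
    counts = _counts(c).astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    factors = np.divide(
        scale_total, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
    )
    data = sp.csc_matrix(counts.multiply(factors.reshape(1, -1)))
    data.data = np.log1p(data.data)
    return _rewrap(view, set_slot(c, data, "data"))


# -- rescaling and signature scores ------------------------------------------


def rescale_minmax(values, to=(0.0, 1.0)) -> np.ndarray:
    """Min-max rescale to ``to``; a zero-range input maps to the midpoint."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("rescale_minmax needs at least one value")
    low, high = to
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full(values.shape, (low + high) / 2.0)
    return (values - vmin) / (vmax - vmin) * (high - low) + low


@dataclass
class SignatureSpec:
    """Positive/negative marker sets and the rescale target interval."""

    positive_features: list[str]
    negative_features: list[str] = field(default_factory=list)
    assay: str | None = None
    slot: str | None = None
    to: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if not (self.positive_features or self.negative_features):
            raise ValueError("signature needs at least one feature")
        if not self.to[0] < self.to[1]:
            raise ValueError(f"invalid rescale interval {self.to}")


def signature_score(view: TidyView, spec: SignatureSpec, out_column: str = "signature_score") -> TidyView:
    """Per-cell signature score written back as an editable column."""
    c = view.backend

    def summed(features) -> np.ndarray:
        if not features:
            return np.zeros(c.n_cells)
        vals = feature_values(c, features, assay=spec.assay, slot=spec.slot)
        return vals.to_numpy().sum(axis=1)

    score = rescale_minmax(summed(spec.positive_features), to=spec.to)
    if spec.negative_features:
        score = score - rescale_minmax(summed(spec.negative_features), to=spec.to)
    return _rewrap(view, set_cell_meta_column(c, out_column, score))


# -- variable features and embedding -----------------------------------------


def _data_slot(container: CellContainer) -> sp.csc_matrix:
    a = container.assay()
    if "data" in a.slots:
        return sp.csc_matrix(a.slots["data"])
    normalized = log_normalize(as_tidy(container))
    return sp.csc_matrix(normalized.backend.assay().slots["data"])


def variable_features(container: CellContainer, k: int) -> list[str]:
    """Top-k feature ids by variance of the normalized slot, ties by input order."""
    feature_ids = container.assay().feature_ids
    if k > len(feature_ids):
        _warnings.warn(
            f"k={k} exceeds {len(feature_ids)} features; returning all", stacklevel=2
        )
        k = len(feature_ids)
    data = _data_slot(container).tocsr()
    n = data.shape[1]
    if n == 0:
        return list(feature_ids)[:k]
    mean = np.asarray(data.mean(axis=1)).ravel()
    sq = data.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    order = np.argsort(-var, kind="stable")
    return [feature_ids[i] for i in order[:k]]


def run_pca(container: CellContainer, n_dims: int, use_features=None) -> CellContainer:
    """Add reduction "pc": truncated SVD scores of the centered normalized slot.

    Deterministic (dense SVD, no randomness); each component's
    largest-magnitude feature loading is made positive.
    """
    feature_ids = container.assay().feature_ids
    if use_features is None:
        use_features = variable_features(container, min(2000, len(feature_ids)))
    index = {f: i for i, f in enumerate(feature_ids)}
    missing = [f for f in use_features if f not in index]
    if missing:
        raise FeatureNotFoundError(missing)
    rows = [index[f] for f in use_features]
    if n_dims > min(container.n_cells, len(rows)):
        raise ShapeError(
            f"n_dims={n_dims} exceeds min(n_cells={container.n_cells}, "
            f"n_features_used={len(rows)})"
        )
    X = np.asarray(_data_slot(container)[rows, :].todense()).T  # cells x features
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_dims] * s[:n_dims]
    loadings = vt[:n_dims]
    for j in range(n_dims):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]
    if "pc" in container.reductions:  # recomputing replaces the old embedding
        container = CellContainer(
            list(container.cell_ids), container.assays, container.active_assay,
            container.cell_meta, container.feature_meta,
            {k: v for k, v in container.reductions.items() if k != "pc"},
        )
    return add_reduction(container, "pc", scores)


# -- polygon gating ----------------------------------------------------------


@dataclass
class Polygon:
    """Simple polygon given as ordered vertices; must enclose nonzero area."""

    vertices: list[tuple[float, float]]

    def __post_init__(self):
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise PolygonError("polygon needs at least 3 vertices")
        xs = np.array([v[0] for v in self.vertices])
        ys = np.array([v[1] for v in self.vertices])
        area = 0.5 * np.abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
        if area == 0:
            raise PolygonError("degenerate polygon (zero area)")

    @classmethod
    def parse(cls, text: str) -> "Polygon":
        """Parse "x1,y1 x2,y2 ..." (CLI/config form)."""
        pairs = [p for p in text.replace(";", " ").split() if p]
        return cls([tuple(map(float, p.split(","))) for p in pairs])


def points_in_polygon(x, y, polygon: Polygon) -> np.ndarray:
    """Even-odd ray-casting containment; edge and vertex points count inside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    boundary = np.zeros(x.shape, dtype=bool)
    verts = polygon.vertices
    for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1]):
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        on_seg = (
            (cross == 0)
            & (x >= min(x1, x2)) & (x <= max(x1, x2))
            & (y >= min(y1, y2)) & (y <= max(y1, y2))
        )
        boundary |= on_seg
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_at)
    return inside | boundary


def gate_polygon(
    view: TidyView, x_column: str, y_column: str, polygon: Polygon, out_column: str = "gate"
) -> TidyView:
    """Boolean gate column from a polygon drawn over two numeric columns."""
    df = materialize_df(view)
    for col in (x_column, y_column):
        if col not in df.columns:
            raise NameError(f"unknown column: {col!r}")
    flags = points_in_polygon(df[x_column].to_numpy(), df[y_column].to_numpy(), polygon)
    return _rewrap(view, set_cell_meta_column(view.backend, out_column, flags))
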