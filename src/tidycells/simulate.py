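"""Synthetic PBMC-like dataset generator.

Counts are negative binomial (variance = mu + mu^2 / dispersion) around
per-cell expected totals drawn from a lognormal library-size distribution.
Expression proportions are shared across cells of a type: a baseline profile
in which the marker features of the owning type are multiplied by
2**marker_log2fc, and mitochondrial features collectively hold
``mito_fraction_mean`` of the mass. Ground truth lands in the container's
metadata: per-cell ``true_type`` and ``sample``, per-feature
``marker_of_type`` and ``is_mito``.

Everything is a pure function of the parameters, so tests never need
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .container import CellContainer, new_container
from .errors import ParamError


@dataclass
class SimParams:
    n_cells: int = 500
    n_features: int = 300
    n_types: int = 3
    markers_per_type: int = 10
    marker_log2fc: float = 2.0
    n_samples: int = 2
    libsize_meanlog: float = float(np.log(2000.0))
    libsize_sdlog: float = 0.3
    nb_dispersion: float = 2.0
    mito_features: int = 10
    mito_fraction_mean: float = 0.1
    type_proportions: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ParamError("nb_dispersion must be > 0")
        if not 0 < self.mito_fraction_mean < 1:
            raise ParamError("mito_fraction_mean must lie in (0, 1)")
        if self.markers_per_type * self.n_types + self.mito_features > self.n_features:
            raise ParamError("markers_per_type * n_types + mito_features exceeds n_features")
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if len(p) != self.n_types or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ParamError("type_proportions must be a simplex vector of length n_types")


def marker_ids(params: SimParams, type_index: int) -> list[str]:
    """Feature ids planted as markers of cell type ``type_index`` (0-based)."""
    return [f"MK{type_index + 1}_{j + 1}" for j in range(params.markers_per_type)]


def _feature_ids(params: SimParams) -> list[str]:
    ids = []
    for t in range(params.n_types):
        ids.extend(f"MK{t + 1}_{j + 1}" for j in range(params.markers_per_type))
    n_other = params.n_features - len(ids) - params.mito_features
    ids.extend(f"gene_{j + 1}" for j in range(n_other))
    ids.extend(f"MT-{j + 1}" for j in range(params.mito_features))
    return ids


def simulate(params: SimParams) -> CellContainer:
    """Draw one dataset; byte-identical across calls for identical params."""
    rng = np.random.default_rng(params.seed)
    n, f = params.n_cells, params.n_features
    feature_ids = _feature_ids(params)
    is_mito = np.array([fid.startswith("MT-") for fid in feature_ids])
    marker_type = np.full(f, 0, dtype=int)  # 0 = not a marker, else 1-based type
    for t in range(params.n_types):
        lo = t * params.markers_per_type
        marker_type[lo : lo + params.markers_per_type] = t + 1

    # baseline expression profile, mito share pinned at mito_fraction_mean
    base = rng.lognormal(mean=0.0, sigma=1.0, size=f)
    base[~is_mito] *= (1.0 - params.mito_fraction_mean) / base[~is_mito].sum()
    if is_mito.any():
        base[is_mito] *= params.mito_fraction_mean / base[is_mito].sum()

    # per-type proportion profiles: markers boosted, then renormalized
    fold = 2.0**params.marker_log2fc
    profiles = np.empty((params.n_types, f))
    for t in range(params.n_types):
        p = base.copy()
        p[marker_type == t + 1] *= fold
        profiles[t] = p / p.sum()

    props = (
        np.full(params.n_types, 1.0 / params.n_types)
        if params.type_proportions is None
        else np.asarray(params.type_proportions, dtype=float)
    )
    types = rng.choice(params.n_types, size=n, p=props)
    samples = rng.integers(0, params.n_samples, size=n)
    libsize = rng.lognormal(params.libsize_meanlog, params.libsize_sdlog, size=n)

    mu = profiles[types] * libsize[:, None]  # cells x features
    theta = params.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)

    cell_ids = [f"cell_{i + 1}" for i in range(n)]
    cell_meta = pd.DataFrame(
        {
            "true_type": [f"type_{t + 1}" for t in types],
            "sample": [f"sample_{s + 1}" for s in samples],
        }
    )
    container = new_container(
        sp.csc_matrix(counts.T), feature_ids, cell_ids, cell_meta, assay_name="RNA"
    )
    container.feature_meta = pd.DataFrame(
        {
            "marker_of_type": [f"type_{t}" if t else "" for t in marker_type],
            "is_mito": is_mito,
        },
        index=pd.Index(feature_ids, name="feature"),
    )
    return container
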