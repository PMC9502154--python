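# tidycells

A tidy tabular abstraction over a hierarchical single-cell expression
container. The back end (`CellContainer`) stores assays features × cells,
cell/feature metadata and named reductions — machine-friendly and bit-exact
with 10x triplet files. The front end (`TidyView`) presents one row per cell:
a `.cell` key column, editable metadata columns and view-only reduction
columns (`PC1`, `UMAP1`, ...).

Grammar-of-data verbs (`mutate`, `filter`, `select`, `arrange`, `slice`,
`sample_cells`, `group_by`, joins, string reshaping, ...) all follow one
protocol: materialize the view, perform an ordinary tabular operation, then
*dispatch*. Dispatch keeps the result container-backed iff

1. no cell was duplicated,
2. the `.cell` key column survives unmodified, and
3. no view-only column was altered;

otherwise the result demotes to a `PlainTable` carrying a structured warning.
Aggregating verbs (`count`, `summarise`, `distinct`, `pull`, `pivot_longer`)
return plain tables or arrays by design.

On top of that sit transcript access (`join_features`, wide or long), the
`nest`/`map_nested`/`unnest` framework for per-group analysis, and an
analysis toolkit: QC columns (library size, detected features, mitochondrial
fraction), log-normalization, min–max rescaling, multi-gene signature
scoring, variance-ranked variable features, a deterministic PCA embedding and
even–odd polygon gating. A negative-binomial PBMC-like simulator with
planted marker genes supplies ground-truth data so nothing is downloaded.

## Quick start

```python
import tidycells as tc
from tidycells import verbs as vb

params = tc.SimParams(n_cells=2000, n_types=3, n_samples=2, seed=0)
view = tc.as_tidy(tc.simulate(params))

view = tc.log_normalize(tc.compute_qc(view))
view = vb.filter(view, "mito_fraction < 0.2")
view = tc.as_tidy(tc.run_pca(view.backend, n_dims=2))

spec = tc.SignatureSpec(positive_features=tc.marker_ids(params, 0),
                        negative_features=tc.marker_ids(params, 1))
view = tc.signature_score(view, spec)

# balanced subsampling across samples
view = vb.count(view, "sample", name="tot_cells", add=True)
view = vb.mutate(view, min_cells=lambda df: df["tot_cells"].min())
n = int(vb.pull(view, "min_cells")[0])
balanced = vb.sample_cells(vb.group_by(view, "sample"), n=n, seed=0)

# per-group analysis
nested = tc.nest(view, "true_type")
nested = tc.map_nested(nested, lambda c: tc.variable_features(c, 6), "top_markers")
```

## CLI

One executable with subcommands, operating on plain-text dataset directories
(`matrix.mtx` + `features.tsv` + `barcodes.tsv` + optional `cell_meta.csv`
and `reductions/*.csv`):

```sh
tidycells simulate --n-cells 2000 --n-types 3 --seed 0 --out data/
tidycells describe data/
tidycells filter data/ --where "total_count > 500" --out filtered/
tidycells sample data/ --per-group sample --n auto --seed 0 --out balanced/
tidycells join-features data/ --features MK1_1,MK1_2 --shape wide --out table.csv
tidycells score data/ --positive MK1_1,MK1_2 --negative MK2_1 --out scored/
tidycells gate scored/ --x PC1 --y PC2 --polygon "0,0 5,0 5,5 0,5" --out gated/
```

`tidycells --config options.yaml <cmd>` loads YAML defaults (display flavor,
reduction-label separator, normalization scale).

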