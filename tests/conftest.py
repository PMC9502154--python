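import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tidycells as tc


@pytest.fixture
def toy_counts():
    """3 features x 2 cells, integer counts."""
    return sp.csc_matrix(np.array([[1, 2], [0, 3], [4, 0]], dtype=np.int64))


@pytest.fixture
def toy_container(toy_counts):
    return tc.new_container(toy_counts, ["g1", "g2", "g3"], ["c1", "c2"])


@pytest.fixture
def table1_container():
    """The 4-cell example table: metadata plus pc/umap reductions."""
    rng = np.random.default_rng(11)
    counts = sp.csc_matrix(rng.integers(0, 6, size=(5, 4)))
    meta = pd.DataFrame(
        {
            "Total count": [10456, 2088, 11309, 8791],
            "Total transcripts": [450, 400, 699, 423],
            "Cluster": [1, 2, 5, 1],
            "Cell type": ["T cell", "B cell", "Monocyte", "Monocyte"],
        }
    )
    c = tc.new_container(
        counts, [f"g{i}" for i in range(5)],
        [f"cell_{i}" for i in range(1, 5)], meta,
    )
    c = tc.add_reduction(c, "pc", np.array([[-1.23], [0.98], [5.55], [-5.42]]))
    c = tc.add_reduction(c, "umap", np.array([[-3.47], [-1.59], [1.26], [-4.42]]))
    return c


@pytest.fixture
def table1_view(table1_container):
    return tc.as_tidy(table1_container)


def make_random_container(seed, n_cells=50, n_features=20, with_reduction=True):
    """Random small container with sample/cluster/value metadata."""
    rng = np.random.default_rng(seed)
    dense = rng.integers(0, 10, size=(n_features, n_cells))
    dense[rng.random(size=dense.shape) < 0.6] = 0  # sparsify
    counts = sp.csc_matrix(dense.astype(np.int64))
    meta = pd.DataFrame(
        {
            "sample": rng.choice(["s1", "s2", "s3"], size=n_cells),
            "cluster": rng.integers(0, 4, size=n_cells),
            "value": np.round(rng.normal(size=n_cells), 6),
        }
    )
    c = tc.new_container(
        sp.csc_matrix(counts),
        [f"g{i}" for i in range(n_features)],
        [f"c{i}" for i in range(n_cells)],
        meta,
    )
    if with_reduction:
        c = tc.add_reduction(c, "pc", rng.normal(size=(n_cells, 2)))
    return c


@pytest.fixture
def random_container():
    return make_random_container


def assert_slots_equal(a: tc.CellContainer, b: tc.CellContainer):
    assert set(a.assays) == set(b.assays)
    for name in a.assays:
        x, y = a.assays[name], b.assays[name]
        assert x.feature_ids == y.feature_ids
        assert set(x.slots) == set(y.slots)
        for slot in x.slots:
            assert (x.slots[slot] != y.slots[slot]).nnz == 0
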