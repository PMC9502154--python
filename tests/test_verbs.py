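import numpy as np
import pandas as pd
import pytest

import tidycells as tc
from tidycells import PlainTable, TidyView
from tidycells import verbs as vb
from tidycells.errors import (
    AggregationError,
    JoinKeyError,
    NameCollisionError,
    ParamError,
    PatternError,
    ReadOnlyColumnError,
    SampleSizeError,
)

from conftest import assert_slots_equal, make_random_container


def df_of(result):
    return result.df if isinstance(result, PlainTable) else tc.materialize(result).df


class TestMutate:
    def test_arithmetic_on_table1(self, table1_view):
        out = vb.mutate(table1_view, double="2 * `Total count`")
        assert isinstance(out, TidyView)
        assert list(df_of(out)["double"]) == [20912, 4176, 22618, 17582]

    def test_key_assignment_demotes(self, table1_view):
        out = vb.mutate(table1_view, **{".cell": '"x"'})
        assert isinstance(out, PlainTable)
        assert len(out.warnings) == 1

    def test_view_only_target_errors(self, table1_view):
        with pytest.raises(ReadOnlyColumnError):
            vb.mutate(table1_view, PC1=0)

    def test_unknown_column_in_expression(self, table1_view):
        with pytest.raises(NameError):
            vb.mutate(table1_view, bad="nonexistent + 1")

    def test_callable_expression(self, table1_view):
        out = vb.mutate(table1_view, half=lambda df: df["Total count"] / 2)
        assert df_of(out)["half"].iloc[0] == 5228.0

    def test_grouped_aggregate_broadcast(self, table1_view):
        grouped = vb.group_by(table1_view, "Cell type")
        out = vb.mutate(grouped, group_min=lambda df: df["Total count"].min())
        # T cell -> 10456, B cell -> 2088, Monocyte -> min(11309, 8791)
        assert list(df_of(out)["group_min"]) == [10456, 2088, 8791, 8791]

    def test_input_backend_untouched(self, table1_view):
        before = table1_view.backend.copy()
        vb.mutate(table1_view, x="Cluster + 1")
        assert table1_view.backend.equals(before)


class TestRename:
    def test_editable_rename(self, table1_view):
        out = vb.rename(table1_view, {"Cluster": "cluster_id"})
        assert isinstance(out, TidyView)
        assert "cluster_id" in out.visible_columns
        assert "Cluster" not in out.visible_columns

    def test_key_rename_demotes(self, table1_view):
        out = vb.rename(table1_view, {".cell": "barcode"})
        assert isinstance(out, PlainTable)
        assert len(out.warnings) == 1

    def test_collision_with_reduction_label(self, table1_view):
        with pytest.raises(NameCollisionError):
            vb.rename(table1_view, {"Cluster": "PC1"})


class TestSelect:
    def test_keep_with_key(self, table1_view):
        out = vb.select(table1_view, [".cell", "Cluster"])
        assert isinstance(out, TidyView)
        assert out.visible_columns == [".cell", "Cluster"]

    def test_drop_key_demotes(self, table1_view):
        out = vb.select(table1_view, ["Cluster"])
        assert isinstance(out, PlainTable)
        assert len(out.warnings) == 1

    def test_key_only_identity_view(self, toy_container):
        view = tc.as_tidy(toy_container)
        out = vb.select(view, [".cell"])
        assert isinstance(out, TidyView)
        assert list(df_of(out)[".cell"]) == ["c1", "c2"]

    def test_unknown_column(self, table1_view):
        with pytest.raises(NameError):
            vb.select(table1_view, [".cell", "nope"])


class TestFilter:
    def test_total_count_threshold(self, table1_view):
        out = vb.filter(table1_view, "`Total count` > 5000")
        assert isinstance(out, TidyView)
        assert list(df_of(out)[".cell"]) == ["cell_1", "cell_3", "cell_4"]

    def test_always_true_identity(self, table1_view):
        out = vb.filter(table1_view, lambda df: np.ones(len(df), dtype=bool))
        assert out.backend.equals(table1_view.backend)

    def test_always_false_zero_cells(self, table1_view):
        out = vb.filter(table1_view, lambda df: np.zeros(len(df), dtype=bool))
        assert isinstance(out, TidyView)
        assert out.n_cells == 0
        assert tc.display_header(out)[0].startswith("# A Cell-table abstraction: 0 ×")

    def test_composition(self, table1_view):
        both = vb.filter(table1_view, "`Total count` > 5000 and Cluster == 1")
        chained = vb.filter(vb.filter(table1_view, "`Total count` > 5000"), "Cluster == 1")
        assert df_of(both).equals(df_of(chained))


class TestSlice:
    def test_single_position(self, table1_view):
        out = vb.slice(table1_view, [2])
        assert isinstance(out, TidyView)
        assert out.backend.cell_ids == ["cell_2"]

    def test_duplicate_positions_demote(self, table1_view):
        out = vb.slice(table1_view, [1, 1])
        assert isinstance(out, PlainTable)

    def test_out_of_range(self, table1_view):
        with pytest.raises(IndexError):
            vb.slice(table1_view, [5])


class TestArrange:
    def test_ascending_order(self, table1_view):
        out = vb.arrange(table1_view, "Total count")
        assert out.backend.cell_ids == ["cell_2", "cell_4", "cell_1", "cell_3"]

    def test_stability_on_ties(self, table1_view):
        out = vb.arrange(table1_view, "Cluster")
        # Cluster values [1, 2, 5, 1]: ties cell_1/cell_4 keep original order
        assert out.backend.cell_ids == ["cell_1", "cell_4", "cell_2", "cell_3"]

    def test_view_only_read_is_legal(self, table1_view):
        out = vb.arrange(table1_view, "PC1")
        assert isinstance(out, TidyView)
        assert out.backend.cell_ids == ["cell_4", "cell_1", "cell_2", "cell_3"]


class TestSampleCells:
    def test_seeded_reproducible(self, table1_view):
        a = vb.sample_cells(table1_view, n=2, seed=7)
        b = vb.sample_cells(table1_view, n=2, seed=7)
        assert isinstance(a, TidyView)
        assert a.backend.cell_ids == b.backend.cell_ids
        assert a.n_cells == 2

    def test_replacement_demotes(self, table1_view):
        out = vb.sample_cells(table1_view, n=3, replace=True, seed=1)
        assert isinstance(out, PlainTable)

    def test_grouped_sizes(self):
        c = make_random_container(21, n_cells=15)
        c = tc.set_cell_meta_column(c, "grp", ["a"] * 5 + ["b"] * 3 + ["c"] * 7)
        grouped = vb.group_by(tc.as_tidy(c), "grp")
        out = vb.sample_cells(grouped, n=3, seed=0)
        assert out.n_cells == 9
        assert df_of(out)["grp"].value_counts().to_dict() == {"a": 3, "b": 3, "c": 3}

    def test_oversample_without_replacement(self, table1_view):
        with pytest.raises(SampleSizeError):
            vb.sample_cells(table1_view, n=5)

    def test_exactly_one_of_n_frac(self, table1_view):
        with pytest.raises(ParamError):
            vb.sample_cells(table1_view)
        with pytest.raises(ParamError):
            vb.sample_cells(table1_view, n=2, frac=0.5)


class TestGroupBy:
    def test_group_then_ungroup(self, table1_view):
        grouped = vb.group_by(table1_view, "Cell type")
        assert grouped.groups == ("Cell type",)
        assert vb.ungroup(grouped).groups == ()

    def test_group_by_view_only_allowed(self, table1_view):
        assert vb.group_by(table1_view, "PC1").groups == ("PC1",)

    def test_unknown_column(self, table1_view):
        with pytest.raises(NameError):
            vb.group_by(table1_view, "nope")

    def test_grouped_summarise_one_row_per_group(self, table1_view):
        out = vb.summarise(
            vb.group_by(table1_view, "Cell type"), n=lambda df: len(df)
        )
        assert isinstance(out, PlainTable)
        assert len(out.df) == 3


class TestCount:
    def test_add_count_broadcasts(self):
        c = make_random_container(22, n_cells=3, with_reduction=False)
        c = tc.set_cell_meta_column(c, "smp", ["A", "A", "B"])
        out = vb.count(tc.as_tidy(c), "smp", name="tot_cells", add=True)
        assert isinstance(out, TidyView)
        assert list(df_of(out)["tot_cells"]) == [2, 2, 1]

    def test_count_table(self):
        c = make_random_container(23, n_cells=3, with_reduction=False)
        c = tc.set_cell_meta_column(c, "smp", ["A", "A", "B"])
        out = vb.count(tc.as_tidy(c), "smp")
        assert isinstance(out, PlainTable)
        assert dict(zip(out.df["smp"], out.df["n"])) == {"A": 2, "B": 1}

    def test_count_empty_view(self, table1_view):
        empty = vb.filter(table1_view, lambda df: np.zeros(len(df), bool))
        out = vb.count(empty, "Cluster")
        assert len(out.df) == 0

    def test_add_count_name_collision(self, table1_view):
        with pytest.raises(NameCollisionError):
            vb.count(table1_view, "Cluster", name="Cluster", add=True)


class TestSummarise:
    def test_mean_total_count(self, table1_view):
        out = vb.summarise(table1_view, mean_count=lambda df: df["Total count"].mean())
        assert isinstance(out, PlainTable)
        assert out.df["mean_count"].iloc[0] == 8161

    def test_empty_view(self, table1_view):
        empty = vb.filter(table1_view, lambda df: np.zeros(len(df), bool))
        out = vb.summarise(empty, x=lambda df: len(df))
        assert len(out.df) <= 1  # ungrouped empty summary

    def test_non_scalar_errors(self, table1_view):
        with pytest.raises(AggregationError):
            vb.summarise(table1_view, bad=lambda df: df["Total count"].to_numpy())


class TestDistinct:
    def test_cell_type_levels(self, table1_view):
        out = vb.distinct(table1_view, "Cell type")
        assert list(out.df["Cell type"]) == ["T cell", "B cell", "Monocyte"]

    def test_key_all_unique(self, table1_view):
        assert len(vb.distinct(table1_view, ".cell").df) == 4

    def test_empty(self, table1_view):
        empty = vb.filter(table1_view, lambda df: np.zeros(len(df), bool))
        assert len(vb.distinct(empty, "Cluster").df) == 0


class TestPull:
    def test_cell_ids(self, table1_view):
        assert list(vb.pull(table1_view, ".cell")) == ["cell_1", "cell_2", "cell_3", "cell_4"]

    def test_reduction_dim(self, table1_view):
        assert list(vb.pull(table1_view, "PC1")) == [-1.23, 0.98, 5.55, -5.42]

    def test_missing(self, table1_view):
        with pytest.raises(NameError):
            vb.pull(table1_view, "missing")


class TestJoinMetadata:
    @pytest.fixture
    def sample_view(self):
        c = make_random_container(31, n_cells=4, with_reduction=False)
        c = tc.set_cell_meta_column(c, "smp", ["A", "A", "B", "C"])
        return tc.as_tidy(c)

    def test_unique_left_join(self, sample_view):
        lookup = PlainTable(pd.DataFrame({"smp": ["A", "B", "C"], "cond": ["x", "y", "z"]}))
        out = vb.join_metadata(sample_view, lookup, by="smp")
        assert isinstance(out, TidyView)
        assert list(df_of(out)["cond"]) == ["x", "x", "y", "z"]

    def test_many_to_many_demotes(self, sample_view):
        lookup = PlainTable(pd.DataFrame({"smp": ["A", "A"], "cond": ["x", "y"]}))
        out = vb.join_metadata(sample_view, lookup, by="smp")
        assert isinstance(out, PlainTable)
        assert len(out.warnings) == 1

    def test_inner_join_subsets_cells(self, sample_view):
        lookup = PlainTable(pd.DataFrame({"smp": ["A", "B"], "cond": ["x", "y"]}))
        out = vb.join_metadata(sample_view, lookup, by="smp", mode="inner")
        assert isinstance(out, TidyView)
        # relational oracle on the densified table
        oracle = tc.materialize(sample_view).df.merge(lookup.df, on="smp", how="inner")
        assert df_of(out)[oracle.columns.tolist()].equals(oracle)

    def test_right_join_unmatched_demotes(self, sample_view):
        lookup = PlainTable(pd.DataFrame({"smp": ["A", "Z"], "cond": ["x", "q"]}))
        out = vb.join_metadata(sample_view, lookup, by="smp", mode="right")
        assert isinstance(out, PlainTable)

    def test_empty_by(self, sample_view):
        with pytest.raises(JoinKeyError):
            vb.join_metadata(sample_view, PlainTable(pd.DataFrame({"smp": []})), by=[])


class TestBindRows:
    def _pair(self, same_features=True):
        a = make_random_container(41, n_cells=3, n_features=5, with_reduction=False)
        b = make_random_container(42, n_cells=2, n_features=5, with_reduction=False)
        b = tc.CellContainer(
            ["x1", "x2"], b.assays, b.active_assay,
            b.cell_meta.reset_index(drop=True), b.feature_meta, b.reductions,
        )
        return tc.as_tidy(a), tc.as_tidy(b)

    def test_disjoint_concat(self):
        a, b = self._pair()
        out = vb.bind_rows(a, b)
        assert isinstance(out, TidyView)
        assert out.n_cells == 5
        dense_a = np.asarray(a.backend.assay().slots["counts"].todense())
        dense_out = np.asarray(out.backend.assay().slots["counts"].todense())
        assert np.array_equal(dense_out[:, :3], dense_a)

    def test_union_zero_fill(self):
        import scipy.sparse as sp

        a = tc.new_container(
            sp.csc_matrix(np.array([[1, 2], [3, 4]])), ["g1", "g2"], ["c1", "c2"]
        )
        b = tc.new_container(
            sp.csc_matrix(np.array([[5], [6]])), ["g2", "g3"], ["d1"]
        )
        out = vb.bind_rows(tc.as_tidy(a), tc.as_tidy(b))
        dense = np.asarray(out.backend.assay().slots["counts"].todense())
        # dense zero-fill oracle over the union feature space [g1, g2, g3]
        oracle = np.array([[1, 2, 0], [3, 4, 5], [0, 0, 6]])
        assert out.backend.assay().feature_ids == ["g1", "g2", "g3"]
        assert np.array_equal(dense, oracle)

    def test_intersect_policy(self):
        import scipy.sparse as sp

        a = tc.new_container(
            sp.csc_matrix(np.array([[1, 2], [3, 4]])), ["g1", "g2"], ["c1", "c2"]
        )
        b = tc.new_container(
            sp.csc_matrix(np.array([[5], [6]])), ["g2", "g3"], ["d1"]
        )
        out = vb.bind_rows(tc.as_tidy(a), tc.as_tidy(b), feature_policy="intersect")
        assert out.backend.assay().feature_ids == ["g2"]

    def test_shared_id_raises(self, table1_view):
        from tidycells.errors import DuplicationError

        with pytest.raises(DuplicationError):
            vb.bind_rows(table1_view, table1_view)

    def test_make_unique_suffixes(self, table1_view):
        out = vb.bind_rows(table1_view, table1_view, make_unique=True)
        assert out.n_cells == 8
        assert len(set(out.backend.cell_ids)) == 8

    def test_data_slot_dropped_with_warning(self):
        a, b = self._pair()
        a = tc.log_normalize(a)
        out = vb.bind_rows(a, b)
        assert "data" not in out.backend.assay().slots
        assert any("data" in str(w) for w in out.warnings)


class TestStringVerbs:
    @pytest.fixture
    def str_view(self):
        c = make_random_container(51, n_cells=2, with_reduction=True)
        c = tc.set_cell_meta_column(c, "sample_rep", ["S1_a", "S2_b"])
        return tc.as_tidy(c)

    def test_separate(self, str_view):
        out = vb.separate(str_view, "sample_rep", into=["smp", "rep"], sep="_")
        assert isinstance(out, TidyView)
        assert list(df_of(out)["smp"]) == ["S1", "S2"]
        assert list(df_of(out)["rep"]) == ["a", "b"]

    def test_unite(self, str_view):
        sep = vb.separate(str_view, "sample_rep", into=["smp", "rep"], sep="_")
        out = vb.unite(sep, "joined", ["smp", "rep"], sep="-")
        assert list(df_of(out)["joined"]) == ["S1-a", "S2-b"]

    def test_extract_regex(self, str_view):
        out = vb.extract_regex(str_view, "sample_rep", into=["num"], pattern=r"S(\d)_")
        assert list(df_of(out)["num"]) == ["1", "2"]

    def test_view_only_target_errors(self, str_view):
        with pytest.raises(ReadOnlyColumnError):
            vb.extract_regex(str_view, "PC1", into=["x"], pattern=r"(\d)")
        with pytest.raises(ReadOnlyColumnError):
            vb.separate(str_view, ".cell", into=["a", "b"], sep="_")

    def test_pattern_without_groups(self, str_view):
        with pytest.raises(PatternError):
            vb.extract_regex(str_view, "sample_rep", into=["x"], pattern=r"S\d")


class TestPivotLonger:
    def test_cardinality(self, table1_view):
        out = vb.pivot_longer(table1_view, ["Total count", "Total transcripts", "Cluster"])
        assert isinstance(out, PlainTable)
        assert len(out.df) == 12

    def test_values_preserved_pairwise(self, table1_view):
        out = vb.pivot_longer(table1_view, ["Total count", "Cluster"])
        wide = tc.materialize(table1_view).df
        # reshape oracle: (cell, name) -> value must match the wide table
        for _, row in out.df.iterrows():
            expected = wide.loc[wide[".cell"] == row[".cell"], row["name"]].iloc[0]
            assert row["value"] == expected

    def test_single_column(self, table1_view):
        assert len(vb.pivot_longer(table1_view, ["Cluster"]).df) == 4


class TestValueSemantics:
    def test_no_verb_mutates_backend(self, table1_view):
        before = table1_view.backend.copy()
        vb.mutate(table1_view, x="Cluster * 2")
        vb.filter(table1_view, "Cluster == 1")
        vb.arrange(table1_view, "Total count")
        vb.rename(table1_view, {"Cluster": "k"})
        vb.select(table1_view, [".cell", "Cluster"])
        vb.pivot_longer(table1_view, ["Cluster"])
        vb.sample_cells(table1_view, n=2, seed=0)
        assert table1_view.backend.equals(before)
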