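"""Single-cell QC thresholds, overexpression arithmetic, binary
subclustering and the DE threshold filter."""

import numpy as np
import pandas as pd
import pytest

from immunopheno.expression import ExpressionMatrix
from immunopheno.single_cell import (
    binary_subcluster,
    celltype_average,
    de_threshold_filter,
    overexpression_calls,
    overexpression_fractions,
    rank_sum_de,
    sc_qc_filter,
)
from immunopheno.synthetic import SyntheticSCConfig, generate_sc_matrix


def _sc(values: np.ndarray, genes=None, cells=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=cells), norm_state=("log2",)
    )


class TestQC:
    def _matrix_with_gene_counts(self, per_cell_expressed, n_genes=250):
        cols = {}
        for ci, n_expr in enumerate(per_cell_expressed):
            v = np.zeros(n_genes)
            v[:n_expr] = 1.0
            cols[f"c{ci}"] = v
        return ExpressionMatrix(
            data=pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]),
            norm_state=("log2",),
        )

    def test_low_gene_cell_removed(self):
        m = self._matrix_with_gene_counts([150, 220, 230])
        out, report = sc_qc_filter(m, min_cells=1)
        assert "c0" not in out.data.columns
        assert report.removed_low_gene_cells == 1

    def test_boundary_200_genes_kept(self):
        m = self._matrix_with_gene_counts([200, 220])
        out, _ = sc_qc_filter(m, min_cells=1)
        assert "c0" in out.data.columns  # "minimum 200" is inclusive

    def test_gene_in_two_cells_removed(self):
        vals = np.ones((250, 4))
        vals[0, 2:] = 0.0  # g0 expressed in 2 of 4 cells
        m = _sc(vals)
        out, report = sc_qc_filter(m)
        assert "g0" not in out.data.index
        assert report.removed_low_cell_genes == 1

    def test_gene_in_three_cells_kept(self):
        vals = np.ones((250, 4))
        vals[0, 3:] = 0.0  # g0 in exactly 3 cells
        out, _ = sc_qc_filter(_sc(vals))
        assert "g0" in out.data.index

    def test_mito_fraction_strictly_under_5_percent(self):
        n_genes = 300
        genes = [f"g{i}" for i in range(n_genes)] + ["MT-0"]
        base = np.ones((n_genes + 1, 2))
        # cell 0: mito 0.06 of total; cell 1: 0.049
        base[-1, 0] = 0.06 / 0.94 * n_genes
        base[-1, 1] = 0.049 / 0.951 * n_genes
        m = ExpressionMatrix(
            data=pd.DataFrame(base, index=genes, columns=["bad", "ok"]),
            norm_state=("log2",),
        )
        out, report = sc_qc_filter(m, min_cells=1)
        assert list(out.data.columns) == ["ok"]
        assert report.removed_high_mito_cells == 1

    def test_empty_result_raises_with_counts(self):
        m = self._matrix_with_gene_counts([10, 20])
        with pytest.raises(ValueError, match="QC removed everything"):
            sc_qc_filter(m)


class TestAverages:
    def test_mean_of_two_cells(self):
        m = _sc(np.array([[1.0, 3.0]]))
        avg = celltype_average(m, pd.Series({"c0": "t", "c1": "t"}))
        assert avg.loc["g0", "t"] == 2.0

    def test_single_cell_type_equals_cell(self):
        m = _sc(np.array([[5.0, 1.0]]))
        avg = celltype_average(m, pd.Series({"c0": "a", "c1": "b"}))
        assert avg.loc["g0", "a"] == 5.0

    def test_all_zero_gene(self):
        m = _sc(np.zeros((1, 3)))
        avg = celltype_average(m, pd.Series({"c0": "a", "c1": "a", "c2": "b"}))
        assert (avg.loc["g0"] == 0).all()

    def test_unlabeled_cell_rejected(self):
        m = _sc(np.ones((1, 2)))
        with pytest.raises(ValueError, match="unlabeled"):
            celltype_average(m, pd.Series({"c0": "a"}))


class TestOverexpression:
    def test_three_type_arithmetic(self):
        avg = pd.DataFrame({"a": [0.0], "b": [2.0], "c": [10.0]}, index=["g"])
        om = overexpression_calls(avg)
        # mean 4, sd sqrt(28) ~ 5.2915, threshold ~ 6.6458
        assert om.thresholds["g"] == pytest.approx(4 + 0.5 * np.sqrt(28.0))
        assert om.calls.loc["g"].tolist() == [0, 0, 1]

    def test_equal_averages_yield_no_calls(self):
        avg = pd.DataFrame({"a": [3.0], "b": [3.0], "c": [3.0]}, index=["g"])
        om = overexpression_calls(avg)
        assert om.calls.loc["g"].sum() == 0  # strict > at threshold == mean

    def test_two_types(self):
        avg = pd.DataFrame({"a": [0.0], "b": [10.0]}, index=["g"])
        om = overexpression_calls(avg)
        assert om.thresholds["g"] == pytest.approx(5 + 0.5 * np.sqrt(50.0))
        assert om.calls.loc["g"].tolist() == [0, 1]

    def test_single_type_rejected(self):
        with pytest.raises(ValueError, match="cell types"):
            overexpression_calls(pd.DataFrame({"a": [1.0]}, index=["g"]))

    def test_minimum_type_never_called_when_sd_positive(self, rng):
        avg = pd.DataFrame(
            rng.normal(size=(50, 5)), columns=list("abcde"),
            index=[f"g{i}" for i in range(50)],
        )
        om = overexpression_calls(avg)
        argmin = avg.to_numpy().argmin(axis=1)
        calls = om.calls.to_numpy()
        assert all(calls[i, argmin[i]] == 0 for i in range(50))


class TestSubclusters:
    def test_separable_binary_patterns(self):
        calls = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1], [0, 1]],
            index=list("abcd"), columns=["t1", "t2"],
        )
        table = binary_subcluster(calls, n_subclusters=2)
        assert table.n_subclusters == 2
        assert table.assignments["a"] == table.assignments["b"]
        assert table.assignments["c"] == table.assignments["d"]
        assert table.assignments["a"] != table.assignments["c"]

    def test_identical_patterns_single_subcluster(self):
        calls = pd.DataFrame([[1, 0]] * 4, index=list("abcd"), columns=["t1", "t2"])
        table = binary_subcluster(calls)
        assert table.n_subclusters == 1 and "identical" in table.note

    def test_three_patterns_complete_linkage(self):
        # d(a,b)=0, d(*,c)=sqrt(2): the 2-cut must isolate c
        calls = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]], index=list("abc"), columns=["t1", "t2"]
        )
        table = binary_subcluster(calls, n_subclusters=2)
        assert table.assignments["a"] == table.assignments["b"] != table.assignments["c"]

    def test_fractions(self):
        calls_df = pd.DataFrame(
            {"microglia": [1, 1, 0, 0], "mdm": [0, 0, 0, 0]},
            index=list("abcd"),
        )
        from immunopheno.single_cell import OverexpressionMatrix

        om = OverexpressionMatrix(
            calls=calls_df, thresholds=pd.Series(0.0, index=calls_df.index)
        )
        table = binary_subcluster(calls_df, n_subclusters=2)
        frac = overexpression_fractions(table, om)
        sub_of_a = table.assignments["a"]
        assert frac.loc[sub_of_a, "microglia"] == pytest.approx(1.0)
        assert (frac["mdm"] == 0).all()


class TestPlantedProgramRecovery:
    def test_full_chain_recovers_planted_pairings(self):
        cfg = SyntheticSCConfig(
            cell_types={"myeloid": 120, "cancer": 120, "t": 120},
            programs={"IC1": (("myeloid",), 2.0), "IC2": (("cancer",), 2.0)},
            n_background_genes=300,
            seed=5,
        )
        m, types, _, clusters = generate_sc_matrix(cfg)
        filtered, _ = sc_qc_filter(m)
        avg = celltype_average(filtered, types)
        calls = overexpression_calls(avg)
        for ic, target in (("IC1", "myeloid"), ("IC2", "cancer")):
            genes = [g for g in clusters[ic] if g in calls.calls.index]
            table = binary_subcluster(calls.calls.loc[genes])
            frac = overexpression_fractions(table, calls)
            # the planted cell type dominates some subcluster's fraction row
            assert (frac.idxmax(axis=1) == target).any()
            assert frac[target].max() >= 0.9


class TestDEThresholds:
    def test_threshold_filter_rules(self):
        stats = pd.DataFrame(
            {
                "logfc": [0.3, 0.25, 0.3, 0.3],
                "pval": [0.01 / 100, 0.01 / 100, 0.001, 0.06 / 100],
            },
            index=["keep", "boundary_lfc", "bonferroni_drop", "p_drop"],
        )
        kept = de_threshold_filter(stats, n_tests=100)
        assert kept == ["keep"]  # 0.25 exactly dropped; 0.001*100=0.1 dropped

    def test_n_tests_validation(self):
        stats = pd.DataFrame({"logfc": [1.0], "pval": [0.01]}, index=["g"])
        with pytest.raises(ValueError, match="n_tests"):
            de_threshold_filter(stats, n_tests=0)

    def test_rank_sum_de_detects_shift(self, rng):
        n = 40
        vals = rng.normal(0.0, 0.3, size=(20, 2 * n))
        vals[0, :n] += 1.0  # g0 up in the group
        m = _sc(vals)
        labels = pd.Series(
            ["grp"] * n + ["rest"] * n, index=m.data.columns
        )
        stats = rank_sum_de(m, labels, "grp")
        kept = de_threshold_filter(stats, n_tests=len(stats))
        assert kept == ["g0"]
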