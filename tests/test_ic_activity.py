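"""Immune gene-cluster activities: variance filter, percentile scaling,
maximum positively-intercorrelated gene group (vs exhaustive enumeration),
and the scaled-median statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immunopheno.expression import ExpressionMatrix
from immunopheno.ic_activity import (
    GeneClusterSet,
    clip_scale_01,
    ic_activity,
    largest_positive_corr_group,
    load_gene_clusters,
    variance_filter,
)


def _expr(rows, state=("log2",)):
    return ExpressionMatrix(data=pd.DataFrame(rows).T, norm_state=state)


class TestVarianceFilter:
    def test_constant_gene_removed(self):
        m = _expr({"g1": [1.0, 1.0, 1.0], "g2": [0.0, 1.0, 2.0]})
        out = variance_filter(m)
        assert list(out.genes) == ["g2"]

    def test_two_sample_variance_half_kept(self):
        m = _expr({"g1": [0.0, 1.0]})
        assert list(variance_filter(m).genes) == ["g1"]  # var 0.5 >= 0.05

    def test_boundary_exactly_min_var_kept(self):
        # sample variance exactly 0.05: values (0, sqrt(0.1)) over 2 samples
        x = np.sqrt(0.1)
        m = _expr({"g1": [0.0, x], "g2": [0.0, 0.0]})
        out = variance_filter(m, min_var=0.05)
        assert list(out.genes) == ["g1"]

    def test_all_removed_raises(self):
        m = _expr({"g1": [1.0, 1.0]})
        with pytest.raises(ValueError, match="all genes"):
            variance_filter(m)


class TestClipScale:
    def test_linear_interpolation_percentiles(self):
        values = np.arange(1.0, 101.0)
        p2, p98 = np.percentile(values, [2, 98])
        assert (p2, p98) == pytest.approx((2.98, 98.02))
        scaled = clip_scale_01(values)
        assert scaled[0] == 0.0 and scaled[-1] == 1.0

    def test_midpoint_value(self):
        values = np.arange(1.0, 101.0)
        scaled = clip_scale_01(values)
        expected = (50.0 - 2.98) / (98.02 - 2.98)
        assert scaled[49] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.4947, abs=1e-4)

    def test_two_point_vector(self):
        scaled = clip_scale_01(np.array([0.0, 1.0]))
        np.testing.assert_allclose(scaled, [0.0, 1.0])

    def test_degenerate_gene_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            clip_scale_01(np.ones(5))


def _exhaustive_max_group(scaled: pd.DataFrame):
    """Independent oracle: enumerate all gene subsets, keep the largest in
    which every pair correlates positively; lexicographic tie-break."""
    genes = list(scaled.index)
    R = pd.DataFrame(
        np.corrcoef(scaled.to_numpy()), index=genes, columns=genes
    )
    best = None
    for r in range(len(genes), 0, -1):
        candidates = [
            sorted(sub)
            for sub in itertools.combinations(genes, r)
            if all(R.loc[a, b] > 0 for a, b in itertools.combinations(sub, 2))
        ]
        if candidates:
            best = min(candidates)
            break
    return best


class TestLargestPositiveGroup:
    def _scaled(self, rows):
        return pd.DataFrame(rows).T

    def test_anticorrelated_gene_excluded(self):
        x = np.linspace(0, 1, 8)
        scaled = self._scaled({"g1": x, "g2": x, "g3": 1 - x})
        group, method = largest_positive_corr_group(scaled)
        assert group == ["g1", "g2"] and method == "exact"

    def test_all_positive_returns_whole_cluster(self, rng):
        base = rng.normal(size=10)
        rows = {f"g{i}": base + rng.normal(0, 0.05, 10) for i in range(5)}
        group, _ = largest_positive_corr_group(self._scaled(rows))
        assert group == [f"g{i}" for i in range(5)]

    def test_triangle_with_one_negative_edge_tie_break(self):
        # r(1,2) > 0, r(2,3) > 0, r(1,3) < 0 -> max clique size 2; {g1,g2}
        # wins the lexicographic tie-break
        g1 = np.array([0.0, 1.0, 2.0, 3.0, 1.0])
        g2 = np.array([0.1, 0.8, 2.2, 2.0, 3.0])
        g3 = np.array([2.0, 1.5, 2.1, 0.0, 3.5])
        scaled = self._scaled({"g1": g1, "g2": g2, "g3": g3})
        R = np.corrcoef(scaled.to_numpy())
        assert R[0, 1] > 0 and R[1, 2] > 0 and R[0, 2] < 0
        group, _ = largest_positive_corr_group(scaled)
        assert group == _exhaustive_max_group(scaled) == ["g1", "g2"]

    def test_no_positive_pair_returns_best_singleton(self):
        x = np.linspace(0, 1, 6)
        scaled = self._scaled({"g1": x, "g2": 1 - x})
        group, method = largest_positive_corr_group(scaled)
        assert len(group) == 1 and method == "singleton"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(4, 10))
        scaled = pd.DataFrame(
            rng.normal(size=(n_genes, 12)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        group, method = largest_positive_corr_group(scaled)
        oracle = _exhaustive_max_group(scaled)
        assert method in ("exact", "singleton")
        if method == "exact":
            assert group == oracle

    def test_greedy_result_is_valid_above_exact_limit(self, rng):
        scaled = pd.DataFrame(
            rng.normal(size=(45, 20)), index=[f"g{i:02d}" for i in range(45)]
        )
        group, method = largest_positive_corr_group(scaled)
        assert method == "greedy"
        R = pd.DataFrame(
            np.corrcoef(scaled.to_numpy()), index=scaled.index, columns=scaled.index
        )
        assert all(
            R.loc[a, b] > 0 for a, b in itertools.combinations(group, 2)
        )


class TestActivity:
    def test_median_of_two_genes(self):
        # two positively-correlated genes; activity = midpoint of their
        # scaled values, checked against a hand-computed clip-scale
        x = np.linspace(1.0, 10.0, 8)
        bulk = _expr({"g1": x, "g2": 2.0 * x})
        act = ic_activity(bulk, {"IC1": ["g1", "g2"]})
        expected = clip_scale_01(x)  # affine-invariant: both genes scale alike
        np.testing.assert_allclose(act.data.loc["IC1"].to_numpy(), expected, atol=1e-12)

    def test_duplicated_gene_cluster_equals_scaled_vector(self, rng):
        x = rng.normal(2.0, 1.0, 12)
        bulk = _expr({f"g{i}": x for i in range(5)})
        act = ic_activity(bulk, {"IC1": [f"g{i}" for i in range(5)]})
        np.testing.assert_allclose(
            act.data.loc["IC1"].to_numpy(), clip_scale_01(x), atol=1e-12
        )

    def test_activities_in_unit_interval(self, rng):
        bulk = _expr({f"g{i}": rng.normal(size=20) for i in range(12)})
        act = ic_activity(
            bulk, {"A": [f"g{i}" for i in range(6)], "B": [f"g{i}" for i in range(6, 12)]}
        )
        vals = act.data.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_rank_preserving_rescaling_invariance(self, rng):
        vals = {f"g{i}": rng.normal(size=15) for i in range(4)}
        bulk1 = _expr(vals)
        bulk2 = _expr({g: 10.0 * v + 3.0 for g, v in vals.items()})
        ics = {"IC1": list(vals)}
        a1 = ic_activity(bulk1, ics).data
        a2 = ic_activity(bulk2, ics).data
        np.testing.assert_allclose(a1.to_numpy(), a2.to_numpy(), atol=1e-9)

    def test_undefined_ic_flagged(self):
        bulk = _expr({"g1": [1.0, 1.0, 1.0, 1.0]})  # constant -> filtered
        act = ic_activity(bulk, {"IC1": ["g1"], "IC2": ["g1"]})
        assert set(act.undefined) == {"IC1", "IC2"}
        assert act.data.isna().all().all()


class TestGeneClusterIO:
    def test_gmt_and_json_roundtrip(self, tmp_path):
        (tmp_path / "c.gmt").write_text("IC1\tdesc\tg1\tg2\nIC2\tdesc\tg3\n")
        gmt = load_gene_clusters(tmp_path / "c.gmt")
        assert gmt["IC1"] == ["g1", "g2"] and gmt["IC2"] == ["g3"]
        (tmp_path / "c.json").write_text('{"IC1": ["g1", "g2"]}')
        js = load_gene_clusters(tmp_path / "c.json")
        assert js["IC1"] == ["g1", "g2"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneClusterSet({"IC1": ["g1", "g1"]})
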