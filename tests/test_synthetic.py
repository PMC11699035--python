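"""Generators: planted-truth bookkeeping, sampling bounds, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from immunopheno.expression import ExpressionMatrix
from immunopheno.single_cell import sc_qc_filter
from immunopheno.synthetic import (
    PopulationSpec,
    SyntheticBulkConfig,
    SyntheticCohortConfig,
    SyntheticSCConfig,
    default_panel,
    default_populations,
    generate_bulk_mixtures,
    generate_event_cohort,
    generate_planted_graph,
    generate_sc_matrix,
    make_reference_profiles,
)


def _single_pop(fraction=1.0, name="only"):
    return PopulationSpec(
        name=name,
        mean_by_channel={"CD45": 3.0},
        sd_by_channel={"CD45": 0.3},
        fraction=fraction,
    )


class TestEventCohort:
    def test_single_population_is_degenerate(self):
        cfg = SyntheticCohortConfig(samples=[("S1", 100, None)], panel=("CD45",), seed=0)
        (table,) = generate_event_cohort(cfg, [_single_pop()])
        assert table.n_events == 100
        assert set(table.truth_labels) == {"only"}

    def test_label_counts_within_binomial_bounds(self):
        pops = [
            PopulationSpec("a", {"CD45": 1.0}, {"CD45": 0.3}, 0.7),
            PopulationSpec("b", {"CD45": 3.0}, {"CD45": 0.3}, 0.2),
            PopulationSpec("c", {"CD45": 5.0}, {"CD45": 0.3}, 0.1),
        ]
        n = 10_000
        cfg = SyntheticCohortConfig(samples=[("S1", n, None)], panel=("CD45",), seed=5)
        (table,) = generate_event_cohort(cfg, pops)
        counts = pd.Series(table.truth_labels).value_counts()
        for name, p in (("a", 0.7), ("b", 0.2), ("c", 0.1)):
            bound = 3 * np.sqrt(n * p * (1 - p))
            assert abs(counts[name] - n * p) < bound

    def test_doublets_are_sums_of_stored_parents(self):
        pops = [_single_pop()]
        cfg = SyntheticCohortConfig(
            samples=[("S1", 1000, None)], panel=("CD45",), doublet_rate=0.1, seed=3
        )
        (table,) = generate_event_cohort(cfg, pops)
        doublets = np.flatnonzero(table.truth_labels == "doublet")
        assert len(doublets) == 100
        vals = table.values()
        for t in doublets:
            a, b = table.doublet_parents[int(t)]
            np.testing.assert_allclose(vals[t], vals[a] + vals[b], rtol=1e-12)

    def test_fraction_sum_validation(self):
        cfg = SyntheticCohortConfig(samples=[("S1", 10, None)], panel=("CD45",), seed=0)
        with pytest.raises(ValueError, match="sum"):
            generate_event_cohort(cfg, [_single_pop(fraction=0.9)])

    def test_unknown_channel_rejected(self):
        bad = PopulationSpec("x", {"CD99": 1.0}, {"CD99": 0.3}, 1.0)
        cfg = SyntheticCohortConfig(samples=[("S1", 10, None)], panel=("CD45",), seed=0)
        with pytest.raises(ValueError, match="CD99"):
            generate_event_cohort(cfg, [bad])

    def test_transform_roundtrip_reproduces_transformed_values(self):
        # raw = sinh(z) * cofactor, so asinh(raw / cofactor) must return z
        cfg = SyntheticCohortConfig(samples=[("S1", 500, None)], panel=default_panel(), seed=7)
        (table,) = generate_event_cohort(cfg, default_populations())
        z = np.arcsinh(table.values() / cfg.cofactor)
        raw_again = np.sinh(z) * cfg.cofactor
        np.testing.assert_allclose(raw_again, table.values(), rtol=1e-6)

    def test_bit_reproducible_under_seed(self):
        cfg = SyntheticCohortConfig(samples=[("S1", 300, None)], panel=default_panel(), seed=9)
        a = generate_event_cohort(cfg, default_populations())[0]
        b = generate_event_cohort(cfg, default_populations())[0]
        assert a.data.equals(b.data)
        assert (a.truth_labels == b.truth_labels).all()


class TestBulkMixtures:
    def _profiles(self):
        profiles, _ = make_reference_profiles(n_genes=60, markers_per_type=8, seed=1)
        return profiles

    def test_pure_weight_recovers_profile(self):
        profiles = self._profiles()
        W = pd.DataFrame([[1.0, 0, 0, 0, 0, 0]], index=["s"], columns=profiles.columns)
        bulk = generate_bulk_mixtures(
            SyntheticBulkConfig(reference_profiles=profiles, mixing_weights=W, noise_sd=0.0)
        )
        np.testing.assert_allclose(
            bulk.data["s"].to_numpy(), np.log2(profiles.iloc[:, 0] + 1.0), rtol=1e-12
        )

    def test_mixture_is_linear(self):
        profiles = self._profiles()
        W = pd.DataFrame([[0.3, 0.7, 0, 0, 0, 0]], index=["s"], columns=profiles.columns)
        bulk = generate_bulk_mixtures(
            SyntheticBulkConfig(reference_profiles=profiles, mixing_weights=W, noise_sd=0.0)
        )
        linear = np.exp2(bulk.data["s"].to_numpy()) - 1.0
        expected = 0.3 * profiles.iloc[:, 0] + 0.7 * profiles.iloc[:, 1]
        np.testing.assert_allclose(linear, expected, rtol=1e-9)

    def test_seeded_determinism_bit_identical(self):
        profiles = self._profiles()
        W = pd.DataFrame(
            np.full((3, 6), 1 / 6), index=list("abc"), columns=profiles.columns
        )
        cfg = SyntheticBulkConfig(reference_profiles=profiles, mixing_weights=W, noise_sd=0.1, seed=4)
        assert generate_bulk_mixtures(cfg).data.equals(generate_bulk_mixtures(cfg).data)

    def test_weight_validation(self):
        profiles = self._profiles()
        W = pd.DataFrame([[0.5, 0.1, 0, 0, 0, 0]], index=["s"], columns=profiles.columns)
        with pytest.raises(ValueError, match="sum"):
            SyntheticBulkConfig(reference_profiles=profiles, mixing_weights=W)


class TestSCMatrix:
    def test_zero_shift_means_no_type_difference(self):
        cfg = SyntheticSCConfig(
            cell_types={"a": 400, "b": 400},
            programs={"P": (("a",), 0.0)},
            n_background_genes=0,
            seed=2,
        )
        m, types, _, clusters = generate_sc_matrix(cfg)
        sub = m.data.loc[clusters["P"]]
        diff = sub.loc[:, (types == "a").to_numpy()].mean(axis=1) - sub.loc[
            :, (types == "b").to_numpy()
        ].mean(axis=1)
        se = cfg.baseline_sd * np.sqrt(2 / 400)
        assert (np.abs(diff) < 4 * se).all()

    def test_planted_shift_recovered_within_3_se(self):
        cfg = SyntheticSCConfig(
            cell_types={"myeloid": 500, "other": 500},
            programs={"P": (("myeloid",), 2.0)},
            n_background_genes=0,
            seed=3,
        )
        m, types, _, clusters = generate_sc_matrix(cfg)
        sub = m.data.loc[clusters["P"]]
        gap = (
            sub.loc[:, (types == "myeloid").to_numpy()].to_numpy().mean()
            - sub.loc[:, (types == "other").to_numpy()].to_numpy().mean()
        )
        se = cfg.baseline_sd * np.sqrt(2 / (500 * len(clusters["P"])))
        assert abs(gap - 2.0) < 3 * se

    def test_high_mito_range_fails_qc_downstream(self):
        cfg = SyntheticSCConfig(
            cell_types={"a": 30, "b": 30},
            programs={},
            n_background_genes=300,
            mito_fraction_range=(0.06, 0.10),
            seed=4,
        )
        m, _, mito, _ = generate_sc_matrix(cfg)
        assert (mito >= 0.05).all()
        with pytest.raises(ValueError, match="QC removed everything"):
            sc_qc_filter(m, min_genes=50)

    def test_unknown_cell_type_in_program(self):
        with pytest.raises(ValueError, match="unknown cell types"):
            SyntheticSCConfig(cell_types={"a": 10}, programs={"P": (("zz",), 1.0)})


class TestPlantedGraph:
    def test_disjoint_triangles(self):
        g, labels = generate_planted_graph(2, 3, p_in=1.0, p_out=0.0, seed=0)
        assert g.n_nodes == 6 and g.n_edges == 6
        u, v = g.edges[:, 0], g.edges[:, 1]
        assert (labels[u] == labels[v]).all()

    def test_seeded_determinism(self):
        g1, _ = generate_planted_graph(3, 50, 0.9, 0.02, seed=42)
        g2, _ = generate_planted_graph(3, 50, 0.9, 0.02, seed=42)
        np.testing.assert_array_equal(g1.edges, g2.edges)

    def test_equal_probabilities_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_graph(2, 5, 0.5, 0.5, seed=0)
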