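"""Synthetic cohort generator: invariants, determinism and moment fidelity."""

import numpy as np
import pandas as pd
import pytest

from modnet import (
    CohortTable,
    InfeasibleTruthError,
    build_truth,
    planted_differences,
    sample_cohort,
)
from modnet.synthetic import PD_FLOOR


class TestPanel:
    def test_layout(self, panel):
        assert panel.n_items == 20
        tags = [it.instrument for it in panel.items]
        assert tags.count("depression") == 9
        assert tags.count("anxiety") == 7
        assert tags.count("functioning") == 4
        assert len(set(panel.item_names)) == 20

    def test_score_ranges(self, panel):
        for it in panel.items:
            expected = (0, 3) if it.instrument in ("depression", "anxiety") else (0, 8)
            assert (it.min_score, it.max_score) == expected

    def test_functioning_items_numbered_two_to_five(self, panel):
        fun = [it.index for it in panel.items if it.instrument == "functioning"]
        assert fun == [2, 3, 4, 5]


class TestBuildTruth:
    def test_null_configuration_has_no_group_structure(self, null_truth):
        assert np.all(null_truth.group_mean_shift == 0)
        assert np.all(null_truth.group_edge_shift == 0)
        assert planted_differences(null_truth) == []

    @pytest.mark.parametrize("density,expected", [(0.1, 19), (0.15, 28), (0.5, 95)])
    def test_base_network_edge_count_matches_density(self, density, expected):
        truth = build_truth(G=11, density=density, seed=2)
        iu = np.triu_indices(20, k=1)
        assert int((truth.base_partial[iu] != 0).sum()) == expected

    def test_planted_magnitudes_and_implied_registry(self):
        truth = build_truth(G=3, n_planted_mean=2, effect_mean=0.5, seed=1)
        assert len(truth.planted_mean_cells) == 2
        assert all(abs(c[2]) == 0.5 for c in truth.planted_mean_cells)
        # each one-group plant implies a difference against the G-1 others
        reg = [d for d in planted_differences(truth) if d["kind"] == "intercept"]
        assert len(reg) == 2 * (3 - 1)
        assert all(abs(d["difference"]) == 0.5 for d in reg)

    def test_precisions_positive_definite_after_repair(self, small_truth):
        for g in range(len(small_truth.groups)):
            eigs = np.linalg.eigvalsh(small_truth.precision(g))
            assert eigs.min() >= PD_FLOOR - 1e-12

    def test_infeasible_configurations_rejected(self):
        with pytest.raises(InfeasibleTruthError):
            build_truth(G=2, n_planted_mean=25, seed=0)
        with pytest.raises(ValueError):
            build_truth(G=1, seed=0)

    def test_roundtrip_json(self, small_truth, tmp_path):
        path = tmp_path / "truth.json"
        small_truth.to_json(path)
        back = type(small_truth).from_json(path)
        assert back.groups == small_truth.groups
        np.testing.assert_allclose(back.base_partial, small_truth.base_partial)
        assert back.planted_mean_cells == small_truth.planted_mean_cells


class TestSampleCohort:
    def test_determinism_bit_identical(self, small_truth):
        a = sample_cohort(small_truth, [50, 40, 30], seed=11)
        b = sample_cohort(small_truth, [50, 40, 30], seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_ordinal_scores_within_panel_ranges(self, small_cohort):
        assert (small_cohort.check_ordinal_ranges()["out_of_range"] == 0).all()
        vals = small_cohort.items_matrix()
        assert np.array_equal(vals, np.rint(vals))

    def test_null_truth_groups_exchangeable(self, null_truth):
        cohort = sample_cohort(null_truth, [5000, 5000], ordinal=False, seed=21)
        items = cohort.items_matrix()
        labels = cohort.data["group"].to_numpy()
        m0 = items[labels == null_truth.groups[0]].mean(axis=0)
        m1 = items[labels == null_truth.groups[1]].mean(axis=0)
        se = items.std(axis=0) * np.sqrt(2 / 5000)
        assert np.all(np.abs(m0 - m1) < 4 * se)

    def test_moment_fidelity_large_n(self, null_truth):
        n = 50_000
        cohort = sample_cohort(null_truth, [n, n], ordinal=False, seed=31)
        sub = cohort.data[cohort.data["group"] == null_truth.groups[0]]
        items = sub[cohort.panel.item_names].to_numpy()
        # configured mean: base + covariate contributions (gender at its rate)
        expected = (
            null_truth.base_mean
            + null_truth.item_scale * 0.67 * null_truth.covariate_effects[1]
        )
        se = items.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(items.mean(axis=0) - expected) < 3.5 * se)

    def test_sample_partials_recover_truth(self, null_truth):
        """Inverting the sample covariance approximates the realized partials."""
        cohort = sample_cohort(null_truth, [50_000, 2], ordinal=False, seed=41)
        sub = cohort.data[cohort.data["group"] == null_truth.groups[0]]
        items = sub[cohort.panel.item_names].to_numpy()
        prec = np.linalg.inv(np.cov(items.T))
        d = np.sqrt(np.diag(prec))
        partial = -prec / np.outer(d, d)
        np.fill_diagonal(partial, 0.0)
        truth_partial = null_truth.partial_realized(0)
        # covariates add a little shared variance; tolerance reflects that
        assert np.abs(partial - truth_partial).max() < 0.05

    def test_rejects_bad_sizes(self, small_truth):
        with pytest.raises(ValueError):
            sample_cohort(small_truth, [10, 0, 10], seed=0)
        with pytest.raises(ValueError):
            sample_cohort(small_truth, [10, 10], seed=0)


class TestPlantedDifferences:
    def test_pair_universe_size(self):
        truth = build_truth(G=11, seed=5)
        pairs = {(a, b) for a in truth.groups for b in truth.groups if a < b}
        assert len(pairs) == 55

    def test_single_edge_plant_appears_for_planted_group_pairs(self):
        truth = build_truth(G=2, n_planted_edge=1, effect_edge=0.3, seed=6)
        reg = planted_differences(truth)
        edges = [d for d in reg if d["kind"] == "edge"]
        assert len(edges) == 1
        assert abs(edges[0]["difference"]) == 0.3


class TestCompleteCase:
    def test_from_raw_drops_incomplete_rows(self, small_cohort):
        raw = small_cohort.data.copy()
        raw.loc[0, "dep1"] = np.nan
        raw.loc[1, "age"] = np.nan
        filtered = CohortTable.from_raw(raw, panel=small_cohort.panel)
        assert filtered.n == small_cohort.n - 2
        assert filtered.n_dropped == 2
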