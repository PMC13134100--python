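"""Nodewise LASSO/EBIC estimator: oracles, invariants, and network assembly."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from modnet import (
    EstimatorSettings,
    build_truth,
    design_matrix,
    ebic_score,
    fit_mnm,
    fit_node,
    sample_cohort,
)
from modnet.estimator import combine_directed, with_rule


class TestSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            EstimatorSettings(gamma=-0.1)
        with pytest.raises(ValueError):
            EstimatorSettings(lambda_path=(0.1, 0.2))  # increasing
        with pytest.raises(ValueError):
            EstimatorSettings(lambda_path_length=1)
        with pytest.raises(ValueError):
            EstimatorSettings(nodewise_rule="XOR")


class TestDesignMatrix:
    @pytest.mark.parametrize("G,expected", [(2, 41), (3, 61)])
    def test_predictor_count(self, G, expected, small_cohort, null_cohort):
        cohort = {2: null_cohort, 3: small_cohort}[G]
        design = design_matrix(cohort, node=0, reference_group=cohort.groups[0])
        assert design.X.shape[1] == expected
        # 19 mains + (G-1) dummies + 19(G-1) interactions + 2 covariates
        assert expected == 19 + (G - 1) + 19 * (G - 1) + 2

    def test_eleven_group_predictor_count(self):
        truth = build_truth(G=11, seed=13)
        cohort = sample_cohort(truth, [30] * 11, seed=14)
        design = design_matrix(cohort, node=5, reference_group="g03")
        assert design.X.shape[1] == 19 + 10 + 190 + 2 == 221

    def test_standardized_columns_unit_variance(self, small_cohort):
        design = design_matrix(small_cohort, 2, small_cohort.groups[0])
        nonconst = design.X.std(axis=0) > 0
        np.testing.assert_allclose(design.X[:, nonconst].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(design.X[:, nonconst].std(axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(design.y.mean(), 0, atol=1e-12)

    def test_unknown_reference_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            design_matrix(small_cohort, 0, "not-a-group")


class TestEbicScore:
    def test_gamma_zero_is_bic(self):
        assert ebic_score(50.0, 100, 3, 40, 0.0) == pytest.approx(
            100 * np.log(0.5) + 3 * np.log(100)
        )

    def test_zero_at_unit_variance_empty_model(self):
        assert ebic_score(rss=200, n=200, df=0, p_candidates=10, gamma=0.5) == 0.0

    def test_df_increment_adds_logn_plus_gamma_term(self):
        n, p, gamma = 500, 60, 0.25
        delta = ebic_score(90.0, n, 4, p, gamma) - ebic_score(90.0, n, 3, p, gamma)
        assert delta == pytest.approx(np.log(n) + 2 * gamma * np.log(p))

    def test_degenerate_rss_rejected(self):
        with pytest.raises(ValueError):
            ebic_score(0.0, 100, 1, 10, 0.25)


class TestFitNode:
    def test_saturating_penalty_gives_empty_model(self, rng):
        X = rng.standard_normal((200, 10))
        y = X[:, 0] * 0.5 + rng.standard_normal(200) + 3.0
        fit = fit_node(X, y, EstimatorSettings(lambda_path=(50.0, 40.0)))
        assert fit.df == 0
        assert np.all(fit.coef == 0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_zero_penalty_matches_least_squares(self, rng):
        n, p = 200, 12
        X = rng.standard_normal((n, p))
        beta = rng.normal(0, 0.5, p)
        y = X @ beta + rng.standard_normal(n)
        fit = fit_node(X, y, EstimatorSettings(lambda_path=(1e-9, 0.0), standardize=False))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, rtol=1e-8, atol=1e-10)

    def test_orthonormal_design_soft_thresholds_ols(self, rng):
        """On a design with X'X = nI the lasso is exact soft-thresholding."""
        n, p = 256, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)  # X'X = n I
        y = rng.standard_normal(n)
        lam = 0.05
        fit = fit_node(X, y, EstimatorSettings(lambda_path=(lam,), standardize=False))
        z = X.T @ y / n
        expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
        np.testing.assert_allclose(fit.coef, expected, rtol=1e-6, atol=1e-8)

    def test_selected_ebic_is_path_minimum(self, small_cohort):
        design = design_matrix(small_cohort, 0, small_cohort.groups[0])
        fit = fit_node(design)
        assert fit.ebic == pytest.approx(fit.ebic_path.min())

    def test_selected_df_bounded_by_densest_path_point(self, small_cohort):
        design = design_matrix(small_cohort, 3, small_cohort.groups[0])
        fit = fit_node(design)
        dense = fit_node(
            design,
            settings=EstimatorSettings(lambda_path=(fit.lambda_path[-1],)),
        )
        assert fit.df <= dense.df


class TestCombineDirected:
    @given(
        v1=st.floats(-1, 1, allow_nan=False),
        v2=st.floats(-1, 1, allow_nan=False),
    )
    @hyp_settings(max_examples=100, derandomize=True)
    def test_and_subset_of_or(self, v1, v2):
        and_present, and_val = combine_directed(v1, v2, "AND")
        or_present, or_val = combine_directed(v1, v2, "OR")
        assert (not and_present) or or_present
        if and_present:
            assert and_val == pytest.approx(0.5 * (v1 + v2))
            assert or_val == and_val

    def test_or_takes_single_nonzero_value(self):
        present, val = combine_directed(0.0, 0.4, "OR")
        assert present and val == 0.4
        present, val = combine_directed(0.0, 0.0, "OR")
        assert not present and val == 0.0


class TestFitMNM:
    def test_null_cohort_strong_penalty_no_edges(self, null_cohort):
        fit = fit_mnm(
            null_cohort,
            null_cohort.groups[0],
            EstimatorSettings(lambda_path=(10.0, 5.0)),
        )
        assert not fit.edge_presence.any()

    def test_group_edges_symmetric_zero_diagonal(self, small_cohort):
        fit = fit_mnm(small_cohort, small_cohort.groups[1])
        np.testing.assert_array_equal(
            fit.group_edges, fit.group_edges.transpose(0, 2, 1)
        )
        for g in range(len(fit.groups)):
            assert np.all(np.diag(fit.group_edges[g]) == 0)

    def test_and_edge_set_subset_of_or(self, small_cohort):
        fit_and = fit_mnm(small_cohort, small_cohort.groups[0])
        fit_or = with_rule(fit_and, "OR")
        assert np.all(fit_or.edge_presence | ~fit_and.edge_presence)

    def test_strong_edge_recovered_with_matching_sign(self):
        """A planted partial of ~0.4 must appear in both groups' networks and
        agree with the inverse-sample-covariance oracle."""
        truth = build_truth(G=2, density=0.02, seed=55)
        # promote one base edge to a strong partial
        iu = np.transpose(np.nonzero(np.triu(truth.base_partial)))
        s, t = iu[0]
        truth.base_partial[s, t] = truth.base_partial[t, s] = 0.4
        truth.__post_init__()
        cohort = sample_cohort(truth, [10_000, 10_000], ordinal=False, seed=56)
        fit = fit_mnm(cohort, "g01")
        assert fit.edge_presence[0, s, t] and fit.edge_presence[1, s, t]
        items = cohort.items_matrix()
        prec = np.linalg.inv(np.cov(items.T))
        d = np.sqrt(np.diag(prec))
        oracle = (-prec / np.outer(d, d))[s, t]
        assert np.sign(fit.group_edges[0, s, t]) == np.sign(oracle)
        assert fit.group_edges[0, s, t] == pytest.approx(oracle, abs=0.07)

    def test_tiny_group_rejected(self, small_truth):
        cohort = sample_cohort(small_truth, [60, 60, 60], seed=77)
        data = cohort.data[cohort.data["group"] != "g03"].copy()
        lone = cohort.data[cohort.data["group"] == "g03"].head(1)
        import pandas as pd

        broken = type(cohort)(
            data=pd.concat([data, lone], ignore_index=True), panel=cohort.panel
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_mnm(broken, "g01")
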