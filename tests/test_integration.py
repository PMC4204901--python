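"""Quintile analysis, segmented regression, 2-D KDE, association tests."""

import numpy as np
import pandas as pd
import pytest

from pcx.core import DataError
from pcx.integration import (kde2d_grid, log2_fold_change,
                             methylation_expression_association, pooled_ttest,
                             quintile_expression_analysis, segmented_fit)


class TestLog2FoldChange:
    def test_identity(self):
        assert log2_fold_change(3.2, 3.2) == 0.0

    def test_floor_makes_zero_over_zero_unity(self):
        assert log2_fold_change(0.0, 0.0, floor=0.1) == 0.0

    def test_exact_power_of_two(self):
        assert log2_fold_change(1.0, 8.0) == pytest.approx(3.0)

    def test_negative_input_raises(self):
        with pytest.raises(DataError):
            log2_fold_change(-1.0, 2.0)


class TestQuintiles:
    @staticmethod
    def _series(values, prefix="g"):
        return pd.Series(values,
                         index=[f"{prefix}{i:04d}" for i in range(len(values))])

    def test_hundred_genes_give_five_bins_of_twenty(self, rng):
        k27 = self._series(rng.normal(size=100))
        expr = self._series(rng.normal(size=100))
        qa = quintile_expression_analysis(k27, expr)
        assert qa.summary["n"].tolist() == [20] * 5

    def test_bin_sizes_differ_by_at_most_one_with_ties(self, rng):
        k27 = self._series(np.zeros(103))  # all tied: id breaks ties
        expr = self._series(rng.normal(size=103))
        qa = quintile_expression_analysis(k27, expr)
        sizes = qa.summary["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103

    def test_membership_is_permutation_invariant_partition(self, rng):
        k27 = self._series(rng.normal(size=80))
        expr = self._series(rng.normal(size=80))
        qa1 = quintile_expression_analysis(k27, expr)
        perm = rng.permutation(80)
        qa2 = quintile_expression_analysis(k27.iloc[perm], expr.iloc[perm])
        pd.testing.assert_series_equal(qa1.membership.sort_index(),
                                       qa2.membership.sort_index())
        assert sorted(qa1.membership.unique()) == [0, 1, 2, 3, 4]

    def test_planted_inverse_relation_detected(self, rng):
        n = 500
        k27 = rng.normal(0, 1, n)
        expr = -0.5 * k27 + rng.normal(0, 0.3, n)
        qa = quintile_expression_analysis(self._series(k27),
                                          self._series(expr))
        top_vs_bottom = qa.tests.query("bin_a == 0 and bin_b == 4").iloc[0]
        assert top_vs_bottom["p"] < 0.01
        assert (qa.summary.loc[4, "median"] < qa.summary.loc[0, "median"])

    def test_constant_expression_gives_zero_t_unit_p(self, rng):
        k27 = self._series(rng.normal(size=50))
        expr = self._series(np.full(50, 1.5))
        qa = quintile_expression_analysis(k27, expr)
        assert (qa.tests["t"] == 0).all()
        assert (qa.tests["p"] == 1).all()

    def test_too_few_genes_raises(self):
        with pytest.raises(DataError):
            quintile_expression_analysis(self._series([1.0, 2.0]),
                                         self._series([0.1, 0.2]))


def grid_search_oracle(x, y, n_grid=4001):
    """Dense profile-RSS grid search over the allowed breakpoint range."""
    lo, hi = np.quantile(x, [0.05, 0.95])
    best = (np.inf, None)
    for psi in np.linspace(lo, hi, n_grid):
        design = np.column_stack([np.ones_like(x), x,
                                  np.maximum(x - psi, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        if rss < best[0]:
            best = (rss, psi)
    return best


class TestSegmented:
    def _broken_stick(self, rng, n=500, psi=-0.5, b_left=0.2, b_right=1.0,
                      noise=0.1):
        x = rng.uniform(-3, 2, n)
        y = (1.0 + b_left * x + (b_right - b_left) * np.maximum(x - psi, 0)
             + rng.normal(0, noise, n))
        return x, y

    def test_pure_line_has_no_slope_change(self, rng):
        x = rng.uniform(-3, 2, 200)
        y = 0.7 * x + 2.0
        fit = segmented_fit(x, y)
        assert abs(fit.slope_right - fit.slope_left) < 1e-6

    def test_recovers_planted_breakpoint_and_slopes(self, rng):
        x, y = self._broken_stick(rng)
        fit = segmented_fit(x, y)
        assert fit.converged
        assert fit.psi == pytest.approx(-0.5, abs=0.1)
        assert fit.slope_left == pytest.approx(0.2, rel=0.2)
        assert fit.slope_right == pytest.approx(1.0, rel=0.2)
        rss_oracle, _ = grid_search_oracle(x, y)
        assert fit.rss <= rss_oracle * (1 + 1e-6)

    def test_far_initial_breakpoint_reaches_same_fit(self, rng):
        x, y = self._broken_stick(rng)
        near = segmented_fit(x, y, psi_init=-0.5)
        far = segmented_fit(x, y, psi_init=2.0)
        assert far.psi == pytest.approx(near.psi, abs=0.05)
        assert far.rss == pytest.approx(near.rss, rel=1e-6)

    def test_rss_never_exceeds_single_line_fit(self, rng):
        for _ in range(5):
            x = rng.uniform(-2, 2, 100)
            y = rng.normal(0, 1, 100)
            fit = segmented_fit(x, y)
            design = np.column_stack([np.ones_like(x), x])
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            rss_line = float(np.sum((y - design @ coef) ** 2))
            assert fit.rss <= rss_line + 1e-9

    def test_degenerate_x_raises(self):
        with pytest.raises(DataError):
            segmented_fit(np.ones(50), np.arange(50.0))


class TestKde2d:
    def test_output_dimensions_and_level_count(self, rng):
        grid = kde2d_grid(rng.normal(size=100), rng.normal(size=100))
        assert grid.density.shape == (50, 50)
        assert len(grid.levels) == 14
        assert (grid.density >= 0).all()
        assert np.all(np.diff(grid.levels) > 0)

    def test_tight_cluster_peaks_at_origin(self, rng):
        x = rng.normal(0, 0.01, 200)
        y = rng.normal(0, 0.01, 200)
        grid = kde2d_grid(x, y)
        i, j = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        assert abs(grid.x[i]) < 0.05 and abs(grid.y[j]) < 0.05

    def test_density_integrates_to_one(self, rng):
        x = rng.normal(0, 1, 300)
        y = rng.normal(2, 0.5, 300)
        grid = kde2d_grid(x, y)
        dx = grid.x[1] - grid.x[0]
        dy = grid.y[1] - grid.y[0]
        assert grid.density.sum() * dx * dy == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_axis_raises(self, rng):
        with pytest.raises(DataError):
            kde2d_grid(np.ones(50), rng.normal(size=50))


class TestAssociation:
    @staticmethod
    def _fixture():
        # 6 CpGs on 4 genes; gene gD is below the expression filter
        assignments = pd.DataFrame({
            "chrom": ["chr1"] * 6,
            "pos": [10, 20, 30, 40, 50, 60],
            "gene_id": ["gA", "gA", "gB", "gC", "gD", "gC"],
        })
        classes = pd.DataFrame({
            "chrom": ["chr1"] * 6,
            "pos": [10, 20, 30, 40, 50, 60],
            "label": ["gain", "gain", "loss", "no_change", "gain", "gain"],
        })
        expr_a = pd.Series({"gA": 1.0, "gB": 2.0, "gC": 4.0, "gD": 0.01})
        expr_b = pd.Series({"gA": 2.0, "gB": 1.0, "gC": 4.0, "gD": 0.02})
        return assignments, classes, expr_a, expr_b

    def test_hand_fixture_class_membership(self):
        assignments, classes, expr_a, expr_b = self._fixture()
        result = methylation_expression_association(assignments, classes,
                                                    expr_a, expr_b)
        # gD excluded by the 0.1 FPKM filter; gain CpGs cover genes gA
        # (twice, deduplicated) and gC
        assert len(result.per_class["gain"]) == 2
        np.testing.assert_allclose(sorted(result.per_class["gain"]),
                                   [0.0, 1.0])
        np.testing.assert_allclose(result.per_class["loss"], [-1.0])
        np.testing.assert_allclose(result.per_class["no_change"], [0.0])

    def test_small_classes_skip_tests_with_notice(self):
        assignments, classes, expr_a, expr_b = self._fixture()
        result = methylation_expression_association(assignments, classes,
                                                    expr_a, expr_b)
        assert ("gain", "loss") in result.skipped
        assert len(result.tests) == 0

    def test_all_no_change_single_distribution_no_tests(self):
        assignments, classes, expr_a, expr_b = self._fixture()
        classes["label"] = "no_change"
        result = methylation_expression_association(assignments, classes,
                                                    expr_a, expr_b)
        assert set(result.per_class) == {"no_change"}
        assert len(result.tests) == 0

    def test_null_cohort_association_not_significant(self, rng):
        n = 400
        assignments = pd.DataFrame({
            "chrom": ["chr1"] * n, "pos": range(n),
            "gene_id": [f"g{i % 100}" for i in range(n)]})
        classes = pd.DataFrame({
            "chrom": ["chr1"] * n, "pos": range(n),
            "label": rng.choice(["gain", "loss", "no_change"], n)})
        expr = pd.Series(rng.lognormal(1, 1, 100),
                         index=[f"g{i}" for i in range(100)])
        expr_b = expr * np.power(2.0, rng.normal(0, 0.5, 100))
        result = methylation_expression_association(assignments, classes,
                                                    expr, expr_b)
        assert (result.tests["p"] > 0.001).all()


class TestPooledTtest:
    def test_matches_scipy_on_regular_data(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        t, p = pooled_ttest(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_equal_constants(self):
        assert pooled_ttest([1, 1, 1], [1, 1]) == (0.0, 1.0)
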