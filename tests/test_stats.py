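"""Group-level inference: ANOVA, permutation tests, FDR, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from neuroemergence import stats


class TestAnova:
    def test_textbook_three_group_table(self):
        gm = stats.GroupedMeasure(
            values=np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float),
            group=["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        )
        res = stats.one_way_anova(gm)
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (2, 6)

    def test_equal_means_give_near_zero_f(self, rng):
        base = rng.normal(size=10)
        vals = np.concatenate([base, base + 0.0, base])
        gm = stats.GroupedMeasure(values=vals, group=["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert stats.one_way_anova(gm).statistic == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        gm = stats.GroupedMeasure(
            values=np.concatenate([a, b]), group=["a"] * 12 + ["b"] * 15
        )
        f = stats.one_way_anova(gm).statistic
        import scipy.stats as sps

        t = sps.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2)

    def test_small_group_errors(self):
        gm = stats.GroupedMeasure(values=np.array([1.0, 2.0, 3.0]), group=["a", "a", "b"])
        with pytest.raises(ValueError):
            stats.one_way_anova(gm)

    def test_observed_f_within_permutation_distribution(self, rng):
        vals = rng.normal(size=24)
        group = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        obs = stats.one_way_anova(stats.GroupedMeasure(values=vals, group=group)).statistic
        perm_f = []
        for _ in range(300):
            perm = rng.permutation(vals)
            perm_f.append(
                stats.one_way_anova(stats.GroupedMeasure(values=perm, group=group)).statistic
            )
        assert min(perm_f) <= obs <= max(perm_f)


class TestPermutationTtest:
    def test_identical_samples(self, rng):
        a = rng.normal(size=15)
        res = stats.permutation_ttest(a, a.copy(), seed=1)
        assert res.p_value > 0.9
        assert res.effect_size == pytest.approx(0.0)

    def test_widely_separated_samples(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20) + 10
        res = stats.permutation_ttest(a, b, seed=2)
        assert res.p_value <= 1e-3

    def test_seed_reproducibility(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.7, 1, 10)
        r1 = stats.permutation_ttest(a, b, seed=7)
        r2 = stats.permutation_ttest(a, b, seed=7)
        assert r1.p_value == r2.p_value

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            stats.permutation_ttest(np.ones(5), np.ones(5))

    def test_type_one_error_calibration(self, rng):
        """Under a true null the rejection rate at alpha=0.05 is ~5%."""
        n_reps, alpha = 200, 0.05
        rejections = 0
        for k in range(n_reps):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            res = stats.permutation_ttest(a, b, n_perm=2000, seed=k)
            rejections += res.p_value < alpha
        assert 0.03 <= rejections / n_reps <= 0.07


class TestBhFdr:
    def test_step_up_by_hand(self):
        adj = stats.bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert stats.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(stats.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_order_invariant(self, rng):
        p = rng.uniform(size=20)
        adj = stats.bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        shuffle = rng.permutation(20)
        assert np.allclose(stats.bh_fdr(p[shuffle]), adj[shuffle])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([])


class TestSummaryStatsTtest:
    def test_cohort_age_comparison(self):
        """Printed group age summaries: t(39) = -0.57, Hedges g = -0.18."""
        res = stats.summary_stats_ttest(35.75, 11.42, 20, 38.24, 15.96, 21)
        assert res.statistic == pytest.approx(-0.57, abs=0.005)
        assert res.df == 39
        assert res.p_value == pytest.approx(0.571, abs=0.001)
        assert res.effect_size == pytest.approx(-0.18, abs=0.005)

    def test_equal_means(self):
        res = stats.summary_stats_ttest(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.summary_stats_ttest(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            stats.summary_stats_ttest(1, 0, 10, 2, 1, 10)


class TestSpearman:
    def test_monotone_pairs(self):
        assert stats.spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert stats.spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_small_table_brute_force(self):
        # ranks of y: {3,1,4,2,5}; rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.5
        res = stats.spearman([1, 2, 3, 4, 5], [3, 1, 4, 2, 5])
        assert res.statistic == pytest.approx(0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            stats.spearman([1, 1, 1], [1, 2, 3])


class TestAncova:
    def test_orthogonal_covariate_leaves_f_close(self, rng):
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15), rng.normal(2, 1, 15)])
        g = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        raw = rng.normal(size=45)
        # orthogonalise the covariate against outcome and group structure so
        # adjustment cannot move the group F materially
        design = np.column_stack(
            [np.ones(45), np.repeat([0, 1, 0], 15), np.repeat([0, 0, 1], 15), y]
        )
        beta, *_ = np.linalg.lstsq(design, raw, rcond=None)
        cov = pd.DataFrame({"motion": raw - design @ beta})
        f_plain = stats.one_way_anova(stats.GroupedMeasure(y, g)).statistic
        f_adj = stats.ancova(stats.GroupedMeasure(y, g, cov)).statistic
        assert abs(f_adj - f_plain) / f_plain < 0.15

    def test_outcome_equal_to_covariate(self, rng):
        y = rng.normal(size=30)
        g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        cov = pd.DataFrame({"c": y})
        res = stats.ancova(stats.GroupedMeasure(y, g, cov))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_constant_covariate_reduces_to_anova(self, rng):
        y = rng.normal(size=24)
        g = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        cov = pd.DataFrame({"c": np.ones(24)})
        f1 = stats.ancova(stats.GroupedMeasure(y, g, cov)).statistic
        f2 = stats.one_way_anova(stats.GroupedMeasure(y, g)).statistic
        assert f1 == pytest.approx(f2)

    def test_collinear_design_names_column(self, rng):
        y = rng.normal(size=20)
        g = ["a"] * 10 + ["b"] * 10
        dummy = np.array([1.0] * 10 + [0.0] * 10)
        cov = pd.DataFrame({"dup": dummy})
        with pytest.raises(ValueError, match="collinear"):
            stats.ancova(stats.GroupedMeasure(y, g, cov))


class TestPosthoc:
    def test_three_comparisons_with_fdr(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(1.5, 1, 10), rng.normal(3, 1, 10)]
        )
        gm = stats.GroupedMeasure(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        table = stats.pairwise_posthoc(gm, n_perm=2000, seed=0)
        assert len(table) == 3
        assert (table["adjusted_p"] >= table["p"] - 1e-12).all()
        assert table.loc[table["comparison"] == "a vs c", "adjusted_p"].iloc[0] < 0.05
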