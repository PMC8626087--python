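"""Statistical battery: ANOVA decompositions against brute-force oracles and
pingouin, sphericity corrections, t-tests, regression and multiplicity."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as ss

from attnet.stats import (
    bonferroni_adjust,
    fc_behavior_regression,
    fdr_bh,
    greenhouse_geisser,
    levene_test,
    mauchly_test,
    mixed_rm_anova,
    one_way_anova,
    pairwise_ttests,
    ttest,
)


class TestOneWay:
    def test_df_for_3_groups_of_10(self, rng):
        vals = rng.standard_normal(30)
        grp = np.repeat(["a", "b", "c"], 10)
        table, _ = one_way_anova(vals, grp)
        row = table["group"]
        assert (row.df1, row.df2) == (2, 27)

    def test_identical_groups_give_zero_F(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        grp = np.repeat(["a", "b", "c"], 3)
        table, _ = one_way_anova(vals, grp)
        assert table["group"].F == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_ss_decomposition_on_toy_data(self):
        vals = np.array([1.0, 2.0, 3.0, 2.0, 4.0, 6.0, 5.0, 7.0, 9.0])
        grp = np.repeat(["a", "b", "c"], 3)
        table, _ = one_way_anova(vals, grp)
        grand = vals.mean()
        ss_b = sum(3 * (vals[i : i + 3].mean() - grand) ** 2 for i in (0, 3, 6))
        ss_w = sum(((vals[i : i + 3] - vals[i : i + 3].mean()) ** 2).sum() for i in (0, 3, 6))
        row = table["group"]
        assert row.ss == pytest.approx(ss_b, rel=1e-12)
        assert row.F == pytest.approx((ss_b / 2) / (ss_w / 6), rel=1e-12)
        assert row.partial_eta_sq == pytest.approx(ss_b / (ss_b + ss_w), rel=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        vals = rng.standard_normal(30)
        grp = np.repeat(["a", "b", "c"], 10)
        table, _ = one_way_anova(vals, grp)
        ref = ss.f_oneway(vals[:10], vals[10:20], vals[20:])
        assert table["group"].F == pytest.approx(ref.statistic, rel=1e-10)
        assert table["group"].p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_brown_forsythe_equals_classical_under_equal_variance(self):
        # with equal n and equal sample variances, BF F* reduces to classical F
        base = np.array([-1.0, 0.0, 1.0])
        vals = np.r_[base + 0.0, base + 1.0, base + 3.0]
        grp = np.repeat(["a", "b", "c"], 3)
        classical, _ = one_way_anova(vals, grp)
        robust, hom = one_way_anova(vals, grp, robust=True)
        assert hom.brown_forsythe_used
        assert robust["group"].F == pytest.approx(classical["group"].F, rel=1e-12)
        assert robust["group"].df2 <= classical["group"].df2 + 1e-9

    def test_heteroscedastic_data_triggers_bf_and_shrinks_df(self, rng):
        vals = np.r_[rng.normal(0, 0.1, 10), rng.normal(0, 5.0, 10), rng.normal(0, 0.1, 10)]
        grp = np.repeat(["a", "b", "c"], 10)
        table, hom = one_way_anova(vals, grp)
        assert hom.brown_forsythe_used
        assert table["group"].correction == "brown-forsythe"
        assert table["group"].df2 < 27


class TestMixedAnova:
    def test_interaction_df_2_27_for_3x10x2(self, rng):
        rows = []
        for g in ["a", "b", "c"]:
            for s in range(10):
                for w in ["pre", "post"]:
                    rows.append(
                        {"subject": f"{g}{s}", "group": g, "within": w, "value": rng.normal()}
                    )
        table, sph = mixed_rm_anova(pd.DataFrame(rows))
        inter = table["group * within"]
        assert (inter.df1, inter.df2) == (2, 27)
        assert sph.gg_epsilon == 1.0  # two within levels: sphericity trivial

    def test_matches_pingouin_on_3x10x4_design(self, balanced_mixed_table):
        table, _ = mixed_rm_anova(balanced_mixed_table)
        ref = pg.mixed_anova(
            balanced_mixed_table,
            dv="value",
            within="within",
            between="group",
            subject="subject",
        )
        ours = {r.effect: r for r in table.rows}
        assert ours["group"].F == pytest.approx(ref.loc[0, "F"], rel=1e-9)
        assert ours["within"].F == pytest.approx(ref.loc[1, "F"], rel=1e-9)
        assert ours["group * within"].F == pytest.approx(ref.loc[2, "F"], rel=1e-9)
        assert ours["group"].ss == pytest.approx(ref.loc[0, "SS"], rel=1e-9)

    def test_mauchly_df_is_5_for_4_within_levels(self, balanced_mixed_table):
        _, sph = mixed_rm_anova(balanced_mixed_table)
        assert sph.df == 5

    def test_ss_decomposition_sums_to_total(self, balanced_mixed_table):
        table, _ = mixed_rm_anova(balanced_mixed_table)
        y = balanced_mixed_table["value"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        parts = (
            sum(r.ss for r in table.rows)
            + table.ss_error["between"]
            + table.ss_error["within"]
        )
        assert parts == pytest.approx(ss_total, rel=1e-8)

    def test_missing_cell_rejected(self, balanced_mixed_table):
        broken = balanced_mixed_table.iloc[:-1]
        with pytest.raises(ValueError, match="within level|incomplete"):
            mixed_rm_anova(broken)

    def test_gg_correction_shrinks_df_and_raises_p_for_f_above_one(self, rng):
        # the conservative direction of the correction holds whenever F >= 1
        # (for F < 1 shrinking both df can lower the tail probability)
        rows = []
        for g in ["a", "b"]:
            for s in range(8):
                base = rng.normal()
                for w in range(4):
                    rows.append(
                        {
                            "subject": f"{g}{s}",
                            "group": g,
                            "within": w,
                            "value": base + 0.6 * w + rng.normal() * (1 + w),
                        }
                    )
        df = pd.DataFrame(rows)
        corrected, sph = mixed_rm_anova(df, gg_always=True)
        uncorrected, _ = mixed_rm_anova(df, sphericity_alpha=0.0, gg_always=False)
        assert sph.gg_epsilon <= 1.0
        for effect in ("within", "group * within"):
            assert corrected[effect].df1 == pytest.approx(
                uncorrected[effect].df1 * sph.gg_epsilon
            )
            if corrected[effect].F >= 1.0:
                assert corrected[effect].p >= uncorrected[effect].p - 1e-12

    def test_interaction_type_I_error_calibrated(self, rng):
        # null 3x6x2 design: rejection rate of the interaction should be ~alpha
        n_rep, alpha, hits = 400, 0.05, 0
        for _ in range(n_rep):
            rows = []
            for g in ["a", "b", "c"]:
                for s in range(6):
                    base = rng.normal()
                    for w in ("x", "y"):
                        rows.append(
                            {"subject": f"{g}{s}", "group": g, "within": w,
                             "value": base + rng.normal()}
                        )
            table, _ = mixed_rm_anova(pd.DataFrame(rows))
            hits += table["group * within"].p < alpha
        rate = hits / n_rep
        assert abs(rate - alpha) < 0.03  # 3-sigma binomial band at 400 reps


class TestSphericity:
    def test_k2_epsilon_is_one(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert greenhouse_geisser(cov) == 1.0

    def test_compound_symmetry_epsilon_is_one(self):
        cov = 0.4 * np.ones((4, 4)) + 0.6 * np.eye(4)
        assert greenhouse_geisser(cov) == pytest.approx(1.0)

    def test_random_covariances_within_bounds_and_match_formula(self, rng):
        for _ in range(20):
            a = rng.standard_normal((6, 4))
            cov = a.T @ a / 6
            eps = greenhouse_geisser(cov)
            k = 4
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12
            # textbook double-centering formula
            centered = cov - cov.mean(0)[None] - cov.mean(1)[:, None] + cov.mean()
            lam = np.linalg.eigvalsh(centered)
            expected = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
            assert eps == pytest.approx(min(1.0, expected), rel=1e-9)

    def test_matches_pingouin_single_group(self, rng):
        wide = rng.standard_normal((12, 4)) * np.array([1.0, 1.2, 1.7, 2.5])
        df = pd.DataFrame(wide, columns=list("wxyz")).reset_index(names="subject")
        long = df.melt(id_vars="subject", var_name="within", value_name="value")
        cov = np.cov(wide, rowvar=False)
        res = mauchly_test(cov, df_error=11)
        ref = pg.sphericity(long, dv="value", within="within", subject="subject")
        assert res.mauchly_w == pytest.approx(ref.W, rel=1e-9)
        assert res.chi_sq == pytest.approx(ref.chi2, rel=1e-9)
        assert res.df == ref.dof
        eps_ref = pg.epsilon(pd.DataFrame(wide), correction="gg")
        assert res.gg_epsilon == pytest.approx(eps_ref, rel=1e-9)


class TestTTests:
    def test_identical_samples_zero(self):
        r = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert r.t == 0.0 and r.cohens_d == 0.0

    def test_paired_n10_df9(self, rng):
        r = ttest(rng.standard_normal(10), rng.standard_normal(10), paired=True)
        assert r.df == 9

    def test_welch_df_matches_satterthwaite_formula(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 4, 15)
        r = ttest(x, y, welch=True)
        vx, vy = x.var(ddof=1) / 10, y.var(ddof=1) / 15
        expected = (vx + vy) ** 2 / (vx**2 / 9 + vy**2 / 14)
        assert r.df == pytest.approx(expected, rel=1e-12)
        pooled = ttest(x, y, welch=False)
        assert r.df < pooled.df

    def test_equal_variance_equal_n_welch_close_to_pooled(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
        assert ttest(x, y, welch=True).df == pytest.approx(
            ttest(x, y, welch=False).df, rel=0.1
        )

    def test_cohens_d_sign_convention(self):
        r = ttest([1.0, 2.0, 3.0], [4.0, 6.0, 5.0], paired=True)
        assert r.cohens_d < 0  # first mean below second

    def test_paired_d_is_mean_diff_over_sd_diff(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        r = ttest(x, y, paired=True)
        d = x - y
        assert r.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_pairwise_bonferroni_adjusts_three_comparisons(self, rng):
        df = pd.DataFrame(
            {
                "value": rng.standard_normal(30),
                "group": np.repeat(["a", "b", "c"], 10),
            }
        )
        res = pairwise_ttests(df, factor="group", correction="bonferroni")
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))


class TestLevene:
    def test_two_identical_groups_statistic_zero(self):
        vals = np.r_[[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        grp = np.repeat(["a", "b"], 3)
        assert levene_test(vals, grp).levene_stat == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_under_null(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            vals = rng.standard_normal(30)
            grp = np.repeat(["a", "b", "c"], 10)
            hits += levene_test(vals, grp).p < 0.05
        assert abs(hits / n_rep - 0.05) < 0.035

    def test_detects_10x_variance_difference(self, rng):
        rejections = 0
        for _ in range(50):
            vals = np.r_[rng.normal(0, 1, 15), rng.normal(0, 10, 15)]
            grp = np.repeat(["a", "b"], 15)
            rejections += levene_test(vals, grp).p < 0.05
        assert rejections >= 45

    def test_median_center_matches_scipy_brown_forsythe(self, rng):
        x, y = rng.standard_normal(12), rng.normal(0, 2, 12)
        res = levene_test(np.r_[x, y], np.repeat(["a", "b"], 12), center="median")
        ref = ss.levene(x, y, center="median")
        assert res.levene_stat == pytest.approx(ref.statistic, rel=1e-12)


class TestRegression:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = fc_behavior_regression(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_equals_r_squared_of_pearson(self, rng):
        x, y = rng.standard_normal(26), rng.standard_normal(26)
        res = fc_behavior_regression(x, y)
        r_ref = ss.pearsonr(x, y)
        assert res.pearson_r == pytest.approx(r_ref.statistic, rel=1e-12)
        assert res.r_squared == pytest.approx(r_ref.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(r_ref.pvalue, rel=1e-9)

    def test_matches_normal_equations_on_5_points(self):
        x = np.array([0.1, 0.4, 0.2, 0.8, 0.5])
        y = np.array([1.0, 2.0, 1.2, 3.1, 2.4])
        res = fc_behavior_regression(x, y)
        X = np.c_[np.ones(5), x]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-10)
        assert res.slope == pytest.approx(beta[1], rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fc_behavior_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMultiplicity:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01]), [0.01])

    def test_bonferroni_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bonferroni_adjust(p)
        assert (adj >= p).all() and (adj <= 1.0).all()

    def test_equal_small_ps_all_discovered(self):
        mask, _ = fdr_bh([0.001] * 10, q=0.05)
        assert mask.all()

    def test_bh_mask_matches_exhaustive_definition(self, rng):
        p = rng.uniform(0, 1, 50) ** 2
        mask, adj = fdr_bh(p, q=0.05)
        # brute-force step-up definition
        order = np.argsort(p)
        k_star = 0
        for k in range(1, 51):
            if p[order[k - 1]] <= 0.05 * k / 50:
                k_star = k
        expected = np.zeros(50, dtype=bool)
        expected[order[:k_star]] = True
        np.testing.assert_array_equal(mask, expected)
        # adjusted p agrees with statsmodels
        from statsmodels.stats.multitest import multipletests

        _, adj_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_ref, atol=1e-12)

    def test_bh_discoveries_superset_of_bonferroni(self, rng):
        p = rng.uniform(0, 0.2, 30)
        mask_bh, _ = fdr_bh(p, q=0.05)
        mask_bonf = bonferroni_adjust(p) < 0.05
        assert np.all(mask_bh | ~mask_bonf)

    def test_bh_monotone_in_q(self, rng):
        p = rng.uniform(0, 1, 40)
        m1, _ = fdr_bh(p, q=0.01)
        m2, _ = fdr_bh(p, q=0.1)
        assert np.all(m2 | ~m1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])
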