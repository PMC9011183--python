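import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from pupilresp import inference as inf


class TestTwoSampleT:
    def test_group_summary_rows_reproduce_printed_demographics(self):
        # age: 10.9 +/- 2.3 (n=18) vs 10.5 +/- 2.9 (n=23)
        r = inf.two_sample_t_from_stats(10.9, 2.3, 18, 10.5, 2.9, 23)
        assert round(r.statistic, 1) == 0.5
        assert r.df == 39
        # performance IQ: 99.0 +/- 17.0 vs 100.4 +/- 14.1
        r2 = inf.two_sample_t_from_stats(99.0, 17.0, 18, 100.4, 14.1, 23)
        assert round(abs(r2.statistic), 1) == 0.3

    def test_identical_groups_null(self):
        r = inf.two_sample_t_from_stats(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_raw_samples(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 17)
        mine = inf.two_sample_t(x, y)
        t, p = stats.ttest_ind(x, y)
        assert mine.statistic == pytest.approx(t, abs=1e-12)
        assert mine.p_value == pytest.approx(p, abs=1e-12)
        w = inf.two_sample_t(x, y, welch=True)
        tw, pw = stats.ttest_ind(x, y, equal_var=False)
        assert w.statistic == pytest.approx(tw, abs=1e-12)
        assert w.p_value == pytest.approx(pw, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            inf.two_sample_t_from_stats(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestPairedT:
    def test_null_and_hand_value(self):
        assert inf.paired_t([0, 0, 0]).statistic == 0.0
        r = inf.paired_t([1, 2, 3])  # mean 2, sd 1, n 3 -> t = 2*sqrt(3)
        assert r.statistic == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2

    def test_not_equivalent_to_two_sample_on_diffs(self, rng):
        # with a size-matched all-zero group the t value happens to coincide,
        # but the reference distribution (df) does not: the tests differ
        d = rng.normal(0.3, 1.0, 9)
        paired = inf.paired_t(d)
        two = inf.two_sample_t(d, np.zeros(9))
        assert paired.df == 8 and two.df == 16
        assert paired.p_value != pytest.approx(two.p_value, rel=1e-6)


class TestAnova:
    def test_no_variance_gives_zero_f(self):
        r = inf.rm_anova_oneway(np.ones((5, 3)))
        assert r.statistic == 0.0

    def test_two_conditions_equal_squared_paired_t(self, rng):
        y = rng.normal(size=(7, 2))
        f = inf.rm_anova_oneway(y)
        t = inf.paired_t(y[:, 0] - y[:, 1])
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-12)

    def test_ss_partition_exact(self, rng):
        y = rng.normal(size=(9, 4))
        n, k = y.shape
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_cond = n * ((y.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((y.mean(1) - grand) ** 2).sum()
        ss_err = ((y - y.mean(0) - y.mean(1)[:, None] + grand) ** 2).sum()
        assert ss_cond + ss_subj + ss_err == pytest.approx(ss_total, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rm_anova_matches_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(5, 12)), int(rng.integers(2, 5))
        y = rng.normal(size=(n, k))
        mine = inf.rm_anova_oneway(y)
        df = pd.DataFrame({"dv": y.ravel(), "cond": np.tile(np.arange(k), n),
                           "subj": np.repeat(np.arange(n), k)})
        aov = pg.rm_anova(df, dv="dv", within="cond", subject="subj",
                          detailed=True, effsize="np2")
        assert mine.statistic == pytest.approx(aov.F[0], abs=1e-9)
        assert mine.p_value == pytest.approx(aov.p_unc[0], abs=1e-9)
        assert mine.effect_size == pytest.approx(aov.np2[0], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mixed_anova_matches_pingouin(self, seed):
        rng = np.random.default_rng(100 + seed)
        n1, n2 = int(rng.integers(4, 9)), int(rng.integers(4, 9))
        y = rng.normal(size=(n1 + n2, 2))
        groups = np.array(["a"] * n1 + ["b"] * n2)
        mine = inf.mixed_anova_2x2(y, groups)
        df = pd.DataFrame({"dv": y.ravel(), "within": np.tile([0, 1], n1 + n2),
                           "subj": np.repeat(np.arange(n1 + n2), 2),
                           "grp": np.repeat(groups, 2)})
        aov = pg.mixed_anova(df, dv="dv", within="within", subject="subj", between="grp")
        for term, src in [("between", "grp"), ("within", "within"),
                          ("interaction", "Interaction")]:
            row = aov[aov.Source == src].iloc[0]
            assert mine[term].statistic == pytest.approx(row.F, abs=1e-9)
            assert mine[term].p_value == pytest.approx(row.p_unc, abs=1e-9)

    def test_mixed_anova_null_and_interaction_structure(self, rng):
        y = np.tile([1.0, 2.0], (10, 1))
        res = inf.mixed_anova_2x2(y, np.array(["a"] * 5 + ["b"] * 5))
        assert res["between"].statistic == pytest.approx(0.0, abs=1e-20)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-20)
        # group difference only in the condition contrast -> interaction, not between
        y2 = np.zeros((40, 2))
        y2[:20, 0], y2[:20, 1] = 0.5, -0.5
        y2[20:, 0], y2[20:, 1] = -0.5, 0.5
        y2 += rng.normal(0, 0.05, y2.shape)
        res2 = inf.mixed_anova_2x2(y2, np.array(["a"] * 20 + ["b"] * 20))
        assert res2["interaction"].p_value < 1e-6
        assert res2["between"].p_value > 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            inf.mixed_anova_2x2(np.zeros((3, 2)), np.array(["a", "a", "b"]))


class TestCorrelationAndChi2:
    def test_pearson_identity_and_orthogonal(self):
        x = np.arange(10.0)
        assert inf.pearson_r(x, x).statistic == pytest.approx(1.0)
        x2 = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y2 = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])
        assert inf.pearson_r(x2, y2).statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_r(self):
        r = inf.pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.statistic == pytest.approx(0.8)
        assert r.df == 3

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        mine = inf.pearson_r(x, y)
        r, p = stats.pearsonr(x, y)
        assert mine.statistic == pytest.approx(r, abs=1e-12)
        assert mine.p_value == pytest.approx(p, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            inf.pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_gender_table_reproduced(self):
        r = inf.chi_square_2x2(3, 15, 7, 15)
        assert round(r.statistic, 1) == 1.2
        assert round(r.p_value, 2) == 0.27

    def test_equal_rows_independent(self):
        assert inf.chi_square_2x2(5, 10, 5, 10).statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 40, 4)
        mine = inf.chi_square_2x2(a, b, c, d)
        ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestBayesFactors:
    def test_null_t_favors_h0(self):
        assert inf.jzs_bf_t(0.0, 18, 23) < 0
        assert inf.jzs_bf_t(0.0, 20, paired=True) < 0

    def test_monotone_in_t(self):
        grid = [inf.jzs_bf_t(t, 15, 17) for t in np.linspace(0, 5, 11)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_reported_age_comparison_value(self):
        # t = 0.48 with groups of 18 and 23 was reported as lgBF ~ -0.5
        assert inf.jzs_bf_t(0.48, 18, 23) == pytest.approx(-0.5, abs=0.1)

    @pytest.mark.parametrize("t,n1,n2", [(0.5, 18, 23), (2.2, 12, 14), (3.4, 30, 30)])
    def test_matches_independent_g_integral(self, t, n1, n2):
        mine = inf.jzs_bf_t(t, n1, n2)
        other = np.log10(float(pg.bayesfactor_ttest(t, n1, n2)))
        assert mine == pytest.approx(other, abs=1e-3)

    def test_prior_collapse_to_null(self):
        # as the prior scale shrinks, H1 degenerates to H0 and lgBF -> 0
        vals = [abs(inf.jzs_bf_t(1.5, 10, 12, prior_scale=s)) for s in (0.5, 0.1, 0.02)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.02

    def test_correlation_bf_matches_pingouin(self):
        for r, n in [(0.1, 40), (-0.03, 42), (0.6, 25)]:
            assert inf.jzs_bf_r(r, n) == pytest.approx(
                np.log10(float(pg.bayesfactor_pearson(r, n))), abs=1e-6
            )

    def test_evidence_labels(self):
        assert inf.evidence_label(3.5).category == "decisive_H1"
        assert inf.evidence_label(-0.5).category == "substantial_H0"
        assert inf.evidence_label(0.5).category == "substantial_H1"
        assert inf.evidence_label(0.0).category == "inconclusive"
        assert inf.evidence_label(-1.5).category == "strong_H0"


class TestPowerSensitivity:
    def test_study_sensitivity_is_point_nine(self):
        d = inf.sensitivity_d(18, 23, 0.05, 0.80)
        assert round(d, 1) == 0.9

    def test_power_equal_alpha_gives_zero(self):
        assert inf.sensitivity_d(18, 23, 0.05, 0.05) == 0.0

    def test_round_trip_inverse(self):
        for n1, n2, a, p in [(18, 23, 0.05, 0.8), (10, 40, 0.01, 0.9)]:
            d = inf.sensitivity_d(n1, n2, a, p)
            assert inf.power_t(d, n1, n2, a) == pytest.approx(p, abs=1e-6)

    def test_power_null_is_alpha(self):
        assert inf.power_t(0.0, 18, 23, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_power_monotone(self):
        assert inf.power_t(0.5, 20, 20) < inf.power_t(0.8, 20, 20)
        assert inf.power_t(0.5, 10, 10) < inf.power_t(0.5, 30, 30)

    def test_large_n_normal_approximation(self):
        n = 10_000
        d = 0.05
        nc = d * np.sqrt(n * n / (2 * n))
        z = stats.norm.ppf(0.975)
        approx = stats.norm.sf(z - nc) + stats.norm.cdf(-z - nc)
        assert inf.power_t(d, n, n) == pytest.approx(approx, abs=1e-3)


class TestAqScore:
    def test_extremes_and_slight_vs_strong(self):
        key = inf.load_aq_key()
        strong = ["strongly " + k for k in key]
        slight = ["slightly " + k for k in key]
        assert inf.aq_score(strong) == 50
        assert inf.aq_score(slight) == 50
        flipped = ["strongly " + ("disagree" if k == "agree" else "agree") for k in key]
        assert inf.aq_score(flipped) == 0

    def test_incomplete_questionnaire_undefined(self):
        key = inf.load_aq_key()
        resp = ["slightly " + k for k in key]
        resp[10] = None
        with pytest.raises(ValueError, match="unanswered"):
            inf.aq_score(resp)
        with pytest.raises(ValueError):
            inf.aq_score(resp[:49] + [])

    def test_levene_sanity(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r = inf.levene_check(x, y)
        assert 0 <= r.p_value <= 1
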