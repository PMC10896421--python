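import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cryoredox.stats import (
    StatsError,
    compare_serum,
    percent_change,
    pool_and_test,
    two_way_anova,
)


def make_table(wt, ko, sexes_wt=None, sexes_ko=None):
    wt, ko = list(wt), list(ko)
    sexes_wt = sexes_wt or ["M", "F"] * (len(wt) // 2 + 1)
    sexes_ko = sexes_ko or ["M", "F"] * (len(ko) // 2 + 1)
    return pd.DataFrame({
        "genotype": ["WT"] * len(wt) + ["KO"] * len(ko),
        "sex": sexes_wt[: len(wt)] + sexes_ko[: len(ko)],
        "mean_rr": wt + ko,
    })


def balanced_table(rng, n_per_cell=4, effects=(0.0, 0.0, 0.0), sd=1.0):
    rows = []
    for g in ("WT", "KO"):
        for s in ("M", "F"):
            mu = (effects[0] * (g == "KO") + effects[1] * (s == "F")
                  + effects[2] * (g == "KO") * (s == "F"))
            for _ in range(n_per_cell):
                rows.append((g, s, rng.normal(mu, sd)))
    return pd.DataFrame(rows, columns=["genotype", "sex", "mean_rr"])


class TestTwoWayAnova:
    def test_matches_statsmodels_type2_on_unbalanced_design(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rows = []
        for g, s, n in [("WT", "M", 11), ("WT", "F", 7),
                        ("KO", "M", 10), ("KO", "F", 6)]:
            for _ in range(n):
                rows.append((g, s, rng.normal(1 + 0.3 * (g == "KO")
                                              + 0.2 * (s == "F"), 0.5)))
        tb = pd.DataFrame(rows, columns=["genotype", "sex", "mean_rr"])
        mine = two_way_anova(tb)
        ref = anova_lm(smf.ols("mean_rr ~ C(genotype)*C(sex)", data=tb).fit(),
                       typ=2)
        assert mine.genotype.F == pytest.approx(ref.loc["C(genotype)", "F"])
        assert mine.sex.F == pytest.approx(ref.loc["C(sex)", "F"])
        assert mine.interaction.F == pytest.approx(
            ref.loc["C(genotype):C(sex)", "F"])
        assert mine.genotype.p == pytest.approx(ref.loc["C(genotype)", "PR(>F)"])

    def test_balanced_design_matches_classical_decomposition(self, rng):
        # from-scratch cell-mean sums of squares for a balanced 2x2
        tb = balanced_table(rng, n_per_cell=5, effects=(0.8, 0.3, 0.1))
        n = 5
        cell = tb.groupby(["genotype", "sex"])["mean_rr"].mean()
        g_mean = tb.groupby("genotype")["mean_rr"].mean()
        s_mean = tb.groupby("sex")["mean_rr"].mean()
        grand = tb["mean_rr"].mean()
        ss_g = 2 * n * ((g_mean - grand) ** 2).sum()
        ss_s = 2 * n * ((s_mean - grand) ** 2).sum()
        ss_i = n * sum(
            (cell[g, s] - g_mean[g] - s_mean[s] + grand) ** 2
            for g in ("WT", "KO") for s in ("M", "F"))
        ss_err = sum(
            ((grp - grp.mean()) ** 2).sum()
            for _, grp in tb.groupby(["genotype", "sex"])["mean_rr"])
        mse = ss_err / (len(tb) - 4)
        res = two_way_anova(tb)
        assert res.genotype.F == pytest.approx(ss_g / mse, rel=1e-10)
        assert res.sex.F == pytest.approx(ss_s / mse, rel=1e-10)
        assert res.interaction.F == pytest.approx(ss_i / mse, rel=1e-10)

    def test_ss_types_coincide_on_balanced_design(self, rng):
        tb = balanced_table(rng, effects=(0.5, 0.2, 0.0))
        r1, r2, r3 = (two_way_anova(tb, ss_type=t) for t in (1, 2, 3))
        assert r1.genotype.F == pytest.approx(r2.genotype.F)
        assert r2.sex.F == pytest.approx(r3.sex.F)

    def test_unbalanced_pure_sex_effect_isolated(self, rng):
        # kidney-like 11M/7F design with a sex effect only: the genotype
        # test stays null while the sex test detects
        g_ps, s_ps = [], []
        for seed in range(60):
            r = np.random.default_rng(seed)
            rows = []
            for g in ("WT", "KO"):
                for s, n in (("M", 11), ("F", 7)):
                    for _ in range(n):
                        rows.append((g, s, r.normal(2.0 * (s == "F"), 1.0)))
            tb = pd.DataFrame(rows, columns=["genotype", "sex", "mean_rr"])
            res = two_way_anova(tb)
            g_ps.append(res.genotype.p)
            s_ps.append(res.sex.p)
        assert np.median(s_ps) < 1e-4
        assert sps.kstest(g_ps, "uniform").pvalue > 0.01

    def test_single_level_factor_rejected(self):
        tb = make_table([1, 2, 3], [4, 5, 6], sexes_wt=["M"] * 3,
                        sexes_ko=["M"] * 3)
        with pytest.raises(StatsError, match="single level"):
            two_way_anova(tb)

    def test_too_small_design_rejected(self):
        tb = make_table([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(StatsError):
            two_way_anova(tb)


class TestPoolAndTest:
    def test_identical_groups_give_t_zero_p_one(self):
        tb = make_table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = pool_and_test(tb, two_way_anova(tb))
        assert res.pooled
        assert res.ttest.t == pytest.approx(0.0, abs=1e-12)
        assert res.ttest.p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # {1,2,3} vs {4,5,6}: pooled-variance t = -3.674, df=4, p ~ 0.021
        tb = make_table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = pool_and_test(tb, two_way_anova(tb))
        assert res.ttest.t == pytest.approx(-3.674, abs=1e-3)
        assert res.ttest.df == 4
        assert res.ttest.p == pytest.approx(0.0213, abs=5e-4)

    def test_t_pvalue_matches_analytic_cdf(self):
        from scipy.integrate import quad
        tb = make_table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = pool_and_test(tb, two_way_anova(tb))
        density = sps.t(res.ttest.df).pdf
        tail, _ = quad(density, abs(res.ttest.t), np.inf)
        assert res.ttest.p == pytest.approx(2 * tail, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_one_sided_p_is_half_two_sided_when_direction_matches(self, seed):
        r = np.random.default_rng(seed)
        tb = make_table(list(r.normal(2, 1, 5)), list(r.normal(1, 1, 5)))
        anova = two_way_anova(tb)
        if not anova.pooling_allowed:
            return
        two = pool_and_test(tb, anova, sidedness="two")
        direction = ("wt_greater" if two.ttest.mean_wt > two.ttest.mean_ko
                     else "ko_greater")
        one = pool_and_test(tb, anova, sidedness="one", direction=direction)
        assert one.ttest.p == pytest.approx(two.ttest.p / 2, rel=1e-12)

    def test_pooling_refused_under_sex_effect(self, rng):
        tb = balanced_table(rng, n_per_cell=10, effects=(0.0, 5.0, 0.0), sd=0.5)
        anova = two_way_anova(tb)
        assert not anova.pooling_allowed
        res = pool_and_test(tb, anova)
        assert not res.pooled and res.ttest is None
        assert set(res.per_sex) == {"M", "F"}
        with pytest.raises(StatsError, match="pooling requested"):
            pool_and_test(tb, anova, force_pool=True)

    def test_welch_variant_differs_under_unequal_variance(self):
        tb = make_table([0.0, 0.1, -0.1, 0.05, -0.05, 0.02],
                        [-3.0, 2.0, 1.0, -2.0, 3.0, -1.0])
        anova = two_way_anova(tb)
        assert anova.pooling_allowed
        student = pool_and_test(tb, anova, t_variant="student")
        welch = pool_and_test(tb, anova, t_variant="welch")
        assert welch.ttest.df < student.ttest.df


class TestPercentChange:
    def test_reported_liver_and_kidney_values(self):
        assert percent_change(2.59, 1.77) == pytest.approx(46.32, abs=0.1)
        assert percent_change(0.85, 0.69) == pytest.approx(23.18, abs=0.1)

    def test_no_change_is_zero(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_wt_baseline_variant(self):
        assert percent_change(2.0, 1.0, baseline="wt") == pytest.approx(50.0)
        assert percent_change(2.0, 1.0, baseline="ko") == pytest.approx(100.0)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_antitone_in_ko_mean(self, wt, ko, delta):
        assert percent_change(wt, ko) > percent_change(wt, ko + delta)

    def test_zero_denominator_rejected(self):
        with pytest.raises(StatsError, match="denominator"):
            percent_change(1.0, 0.0)


class TestCompareSerum:
    def test_recovers_generated_glucose_elevation(self):
        from cryoredox.synthetic import SerumSpec, generate_serum_table
        changes = []
        for seed in range(60):
            spec = SerumSpec(
                analytes=[("glucose", 180.0, "mg/dL", 1.238, 0.1)],
                n_per_group=10, rng_seed=seed)
            table = generate_serum_table(spec)
            res = compare_serum(table, "glucose")
            if res.pooled:
                # serum elevations are KO over WT: WT-baseline convention
                changes.append(-percent_change(res.ttest.mean_wt,
                                               res.ttest.mean_ko,
                                               baseline="wt"))
        assert np.median(changes) == pytest.approx(23.8, abs=3.0)

    def test_missing_analyte_rejected(self):
        from cryoredox.synthetic import SerumSpec, generate_serum_table
        table = generate_serum_table(
            SerumSpec(analytes=[("BUN", 20.0, "mg/dL", 1.0, 0.1)],
                      n_per_group=5))
        with pytest.raises(StatsError, match="not present"):
            compare_serum(table, "glucose")

    def test_single_animal_group_rejected(self):
        tb = pd.DataFrame({
            "genotype": ["WT", "WT", "KO"],
            "sex": ["M", "F", "M"],
            "analyte": ["x"] * 3,
            "value": [1.0, 2.0, 3.0],
        })
        with pytest.raises(StatsError):
            compare_serum(tb, "x")
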