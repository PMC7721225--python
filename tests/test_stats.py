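import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitpls.stats import (
    ancova_group_effect,
    baseline_network_anova,
    independent_t,
    match_on_severity,
    mixed_anova,
    tukey_posthoc,
)


class TestIndependentT:
    def test_hand_computed_example(self):
        # {1,2,3} vs {4,5,6}: pooled SD 1, SE sqrt(2/3), t = -3/sqrt(2/3)
        res = independent_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert res.df == 4
        assert res.p == pytest.approx(0.021312, abs=1e-5)
        assert res.mean_difference == pytest.approx(-3.0)

    def test_identical_groups_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            independent_t([2.0, 2.0], [2.0, 2.0])

    def test_welch_df_below_pooled_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 30)
        pooled = independent_t(a, b)
        welch = independent_t(a, b, welch=True)
        assert welch.df < pooled.df

    def test_shift_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 7.0]
        r1 = independent_t(a, b)
        r2 = independent_t([x + 100 for x in a], [x + 100 for x in b])
        assert r1.t == pytest.approx(r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_f_equals_t_squared_against_oneway(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = independent_t(a, b)
        F, p = sps.f_oneway(a, b)
        assert res.t**2 == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestMatching:
    def test_trims_lowest_severity_from_larger_group(self, default_cohort):
        res = match_on_severity(default_cohort.subjects)
        assert res.n_removed == 9
        assert len(res.kept_ids["freezer"]) == 21
        assert len(res.kept_ids["nonfreezer"]) == 21
        # every removed nonfreezer scores at or below every kept nonfreezer
        by_id = {s.id: s for s in default_cohort.subjects}
        removed_max = max(by_id[i].updrs_iii for i in res.removed_ids)
        kept_min = min(by_id[i].updrs_iii for i in res.kept_ids["nonfreezer"])
        assert removed_max <= kept_min
        assert 0 <= res.post_match_p <= 1

    @staticmethod
    def _toy_records():
        from gaitpls.gait import SubjectRecord

        def rec(sid, group, updrs):
            return SubjectRecord(
                id=sid, group=group, arm="exercise_first",
                speeds={("baseline", "single"): 1.0, ("baseline", "dual"): 0.9},
                updrs_iii=updrs, nfogq=3.0 if group == "freezer" else None,
            )

        return [
            rec("F1", "freezer", 40.0),
            rec("F2", "freezer", 50.0),
            rec("N1", "nonfreezer", 30.0),  # tied with N2; id breaks the tie
            rec("N2", "nonfreezer", 30.0),
            rec("N3", "nonfreezer", 45.0),
        ]

    def test_tie_broken_by_id(self):
        res = match_on_severity(self._toy_records())
        assert res.removed_ids == ["N1"]

    def test_equal_sizes_warns(self):
        recs = [r for r in self._toy_records() if r.id != "N3"]
        with pytest.warns(UserWarning, match="no-op"):
            match_on_severity(recs)


class TestMixedAnova:
    def test_hand_sums_of_squares_2x2(self):
        # 2 groups x 2 times, 2 subjects per group; worked by hand:
        # values chosen so every SS is a simple fraction
        vals = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0], [4.0, 6.0]])
        group = np.array(["a", "a", "b", "b"])
        out = mixed_anova(vals, group)
        # grand mean 3.25; group means 2.0 vs 4.5 -> ss_group = 2*2*(1.25^2)*2
        assert out.loc["group", "ss"] == pytest.approx(12.5)
        # time means 2.5 vs 4.0 -> ss_time = 4 * (0.75^2) * 2
        assert out.loc["time", "ss"] == pytest.approx(4.5)
        # interaction: a rises by 1, b rises by 2 -> ss = 0.5
        assert out.loc["group x time", "ss"] == pytest.approx(0.5)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        n = 16
        vals = rng.normal(size=(n, 3)) + np.array([0.0, 0.5, 1.0])
        group = np.array(["a"] * 8 + ["b"] * 8)
        vals[group == "b"] += 0.7
        mine = mixed_anova(vals, group)
        long = pd.DataFrame(
            {
                "y": vals.ravel(),
                "subj": np.repeat(np.arange(n), 3),
                "time": np.tile(["t1", "t2", "t3"], n),
                "grp": np.repeat(group, 3),
            }
        )
        ref = pg.mixed_anova(
            data=long, dv="y", within="time", subject="subj", between="grp"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-8)
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert mine.loc["group x time", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8
        )
        assert mine.loc["group", "p"] == pytest.approx(
            ref.loc["grp", "p_unc"], rel=1e-8
        )

    def test_all_equal_input_gives_zero_f(self):
        vals = np.full((6, 2), 3.0)
        group = np.array(["a"] * 3 + ["b"] * 3)
        out = mixed_anova(vals, group)
        assert (out["F"] == 0).all()
        assert (out["p"] == 1).all()

    def test_missing_cell_rejected(self):
        vals = np.full((4, 2), 1.0)
        vals[0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(vals, ["a", "a", "b", "b"])

    def test_baseline_network_anova_labels(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(2.5, 0.1, size=(8, 5))
        out = baseline_network_anova(vals, ["a"] * 4 + ["b"] * 4)
        assert list(out.index) == ["group", "network", "group x network"]


class TestAncova:
    def test_orthogonal_covariate_matches_nested_model_oracle(self):
        rng = np.random.default_rng(4)
        n = 40
        group = np.array(["a"] * 20 + ["b"] * 20)
        x = rng.normal(size=n)
        x = x - x.mean()
        # make covariate exactly orthogonal to group coding
        x[group == "a"] -= x[group == "a"].mean()
        x[group == "b"] -= x[group == "b"].mean()
        y = 1.0 * (group == "b") + 0.5 * x + rng.normal(0, 0.5, n)
        res = ancova_group_effect(y, group, x)
        # nested-model F oracle: compare residual SS with and without group
        A_full = np.column_stack([np.ones(n), group == "b", x])
        A_red = np.column_stack([np.ones(n), x])
        rss_full = np.sum(
            (y - A_full @ np.linalg.lstsq(A_full, y, rcond=None)[0]) ** 2
        )
        rss_red = np.sum(
            (y - A_red @ np.linalg.lstsq(A_red, y, rcond=None)[0]) ** 2
        )
        F_oracle = (rss_red - rss_full) / (rss_full / (n - 3))
        assert res["F"] == pytest.approx(F_oracle, rel=1e-8)
        assert res["df1"] == 1 and res["df2"] == n - 3
        assert res["p"] == pytest.approx(sps.f.sf(F_oracle, 1, n - 3), rel=1e-8)

    def test_covariate_explaining_group_difference_kills_effect(self):
        rng = np.random.default_rng(5)
        n = 60
        group = np.array(["a"] * 30 + ["b"] * 30)
        x = rng.normal(size=n) + 2.0 * (group == "b")
        y = 1.5 * x + rng.normal(0, 0.3, n)  # group acts only through x
        adjusted = ancova_group_effect(y, group, x)
        raw = independent_t(y[group == "a"], y[group == "b"])
        assert raw.p < 0.001  # unadjusted difference is large
        assert adjusted["p"] > 0.05  # adjusting for x removes it

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova_group_effect(
                [1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], [1.0] * 4
            )


class TestTukey:
    def test_two_cells_q_equals_t_times_sqrt2(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        res = independent_t(a, b)
        ms_error = (a.var(ddof=1) + b.var(ddof=1)) / 2
        out = tukey_posthoc(
            [a.mean(), b.mean()], ms_error, df_error=18, ns=[10, 10]
        )
        assert out.loc[0, "q"] == pytest.approx(abs(res.t) * np.sqrt(2), rel=1e-10)
        # with k=2 the studentized-range p equals the two-sided t p
        assert out.loc[0, "p_adj"] == pytest.approx(res.p, rel=1e-6)

    def test_critical_value_matches_table(self):
        # classic table value: q(0.05; k=3, df=12) = 3.77
        q_crit = sps.studentized_range.ppf(0.95, 3, 12)
        assert q_crit == pytest.approx(3.77, abs=0.01)
        out = tukey_posthoc([0.0, 0.0, 3.77], ms_error=2.0, df_error=12,
                            ns=[5, 5, 5])
        # cell 0 vs cell 2: q = 3.77 / sqrt(2/2 * 2/5) -> compute directly
        se = np.sqrt(2.0 / 2.0 * (1 / 5 + 1 / 5))
        assert out.loc[1, "q"] == pytest.approx(3.77 / se, rel=1e-10)

    def test_identical_means_give_p_one(self):
        out = tukey_posthoc([1.0, 1.0, 1.0], 0.5, 10, [4, 4, 4])
        assert (out["q"] == 0).all()
        assert (out["p_adj"] == 1.0).all()
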