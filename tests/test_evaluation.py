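import dataclasses
import itertools
from math import comb

import numpy as np
import pytest

from gaitpls import CohortSpec, generate_cohort, network_block, planted_beta_for_r2
from gaitpls.evaluation import (
    EvalDistributions,
    _split_mse,
    _unrank_combination,
    comparison_p,
    cv_null,
    cv_real,
    effect_size,
    empirical_p,
    plan_splits,
    pooled_r2,
    screen_networks,
)


class TestPlanSplits:
    @pytest.mark.parametrize("n,expected", [(21, 1330), (30, 4060), (4, 4)])
    def test_exhaustive_counts(self, n, expected):
        plan = plan_splits(n, holdout=3, cap=10_000)
        assert comb(n, 3) == expected
        assert len(plan.splits) == expected
        assert plan.exhaustive

    def test_exhaustive_matches_itertools_order(self):
        plan = plan_splits(7, holdout=3, cap=10_000)
        assert plan.splits == tuple(itertools.combinations(range(7), 3))

    def test_unranking_bijective(self):
        for n, k in [(6, 3), (10, 2), (8, 4)]:
            ref = list(itertools.combinations(range(n), k))
            got = [_unrank_combination(r, n, k) for r in range(comb(n, k))]
            assert got == ref

    def test_sampled_plan_distinct_sorted_and_seeded(self):
        plan = plan_splits(40, holdout=3, cap=500, seed=7)
        assert not plan.exhaustive
        assert len(plan.splits) == 500
        assert len(set(plan.splits)) == 500
        for s in plan.splits:
            assert s[0] < s[1] < s[2] < 40
        again = plan_splits(40, holdout=3, cap=500, seed=7)
        assert plan.splits == again.splits
        other = plan_splits(40, holdout=3, cap=500, seed=8)
        assert plan.splits != other.splits

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            plan_splits(3, holdout=3)


class TestCvReal:
    def test_noiseless_signal_near_zero_mse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.3]) + 3.0
        plan = plan_splits(12, holdout=3)
        dist = cv_real(X, y, plan, k=4)
        assert dist.mses.max() < 1e-12
        assert pooled_r2(dist, y) == pytest.approx(1.0, abs=1e-10)

    def test_each_subject_held_out_choose_n_minus_1_2_times(self):
        rng = np.random.default_rng(1)
        n = 10
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        dist = cv_real(X, y, plan_splits(n, holdout=3), k=2)
        np.testing.assert_array_equal(dist.holdout_counts, np.full(n, comb(n - 1, 2)))

    def test_noise_only_mse_matches_independent_oracle(self):
        # pure-noise outcome: compare the mean held-out MSE against a
        # Monte-Carlo oracle built on sklearn's PLS at the same (n, p, k)
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        n, p, k = 15, 8, 3
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        plan = plan_splits(n, holdout=3)
        mine = cv_real(X, y, plan, k=k).mses.mean()

        oracle_mses = []
        for test_idx in plan.splits:
            mask = np.ones(n, dtype=bool)
            mask[list(test_idx)] = False
            ref = PLSRegression(n_components=k, scale=False).fit(X[mask], y[mask])
            pred = ref.predict(X[list(test_idx)]).ravel()
            oracle_mses.append(np.mean((pred - y[list(test_idx)]) ** 2))
        assert mine == pytest.approx(np.mean(oracle_mses), rel=1e-8)

    def test_too_many_components_for_training_size_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="components"):
            cv_real(rng.normal(size=(6, 5)), rng.normal(size=6),
                    plan_splits(6, holdout=3), k=4)


class TestCvNull:
    def test_identity_permutation_equals_unpermuted_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        test_idx = (1, 4, 7)
        plain, _ = _split_mse(X, y, test_idx, k=2)
        ident, _ = _split_mse(X, y, test_idx, k=2, train_perm=np.arange(7))
        assert plain == ident

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        a = cv_null(X, y, n_null=50, k=2, seed=42)
        b = cv_null(X, y, n_null=50, k=2, seed=42)
        np.testing.assert_array_equal(a.mses, b.mses)
        c = cv_null(X, y, n_null=50, k=2, seed=43)
        assert not np.array_equal(a.mses, c.mses)

    def test_effect_size_near_zero_under_independence(self):
        # when the outcome is pure noise, permuting training labels changes
        # nothing distributionally, so real vs null effect size averages ~0
        # per-dataset d has SD ~0.44, so average over 30 datasets and allow
        # three standard errors (0.44 / sqrt(30) * 3 ~ 0.25)
        rng = np.random.default_rng(6)
        ds = []
        for rep in range(30):
            X = rng.normal(size=(12, 5))
            y = rng.normal(size=12)
            real = cv_real(X, y, plan_splits(12, holdout=3), k=2)
            null = cv_null(X, y, n_null=400, k=2, seed=rep)
            ds.append(effect_size(real.mses, null.mses))
        assert abs(np.mean(ds)) < 0.25


class TestSummaryStatistics:
    def test_effect_size_hand_example(self):
        # means 2 vs 4, each sample variance 1 -> pooled SD 1 -> d = 2
        assert effect_size([1.0, 2.0, 3.0], [3.0, 4.0, 5.0]) == pytest.approx(2.0)

    def test_effect_size_sign_convention(self):
        # lower real error than null -> positive d
        assert effect_size([1.0, 1.1, 0.9], [2.0, 2.2, 1.8]) > 0
        assert effect_size([2.0, 2.2, 1.8], [1.0, 1.1, 0.9]) < 0

    def test_effect_size_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero pooled"):
            effect_size([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="empty"):
            effect_size([], [1.0])

    def test_empirical_p_boundaries(self):
        # no null value at or below the real mean -> smallest attainable p
        assert empirical_p([1.0, 1.0], [2.0] * 99) == pytest.approx(1 / 100)
        # every null value below the real mean -> p = 1
        assert empirical_p([5.0, 5.0], [1.0] * 99) == pytest.approx(1.0)

    def test_empirical_p_counts_ties_as_extreme(self):
        assert empirical_p([2.0], [2.0, 3.0, 4.0]) == pytest.approx(2 / 4)

    def test_empirical_p_near_half_under_exchangeability(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(50):
            pool = rng.normal(size=600)
            ps.append(empirical_p(pool[:300], pool[300:]))
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_comparison_p_matches_scipy_welch(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 0.3, 200)
        b = rng.normal(1.2, 0.4, 300)
        ref = stats.ttest_ind(a, b, equal_var=False, alternative="less").pvalue
        assert comparison_p(a, b) == pytest.approx(ref, rel=1e-12)

    def test_comparison_p_direction(self):
        rng = np.random.default_rng(9)
        low = rng.normal(1.0, 0.2, 500)
        high = rng.normal(2.0, 0.2, 500)
        assert comparison_p(low, high) < 1e-6
        assert comparison_p(high, low) > 0.999

    def test_pooled_r2_requires_predictions(self):
        with pytest.raises(ValueError, match="pooled predictions"):
            pooled_r2(EvalDistributions(np.array([1.0])), [1.0, 2.0, 3.0])


class TestScreenNetworks:
    def test_planted_network_ranks_first_without_shared_subject_effect(
        self, canonical_parcellation
    ):
        # subject_effect_sd=0 removes the global component that couples
        # network means, so signal should localize to the planted network;
        # the shared offsets are zeroed too so the calibrated association
        # does not displace every subject's improvement by a constant. The
        # remaining per-column signal is weak (it rides only on measurement
        # noise), so a larger sample is needed to localize it.
        spec = CohortSpec(
            n_freezers=100,
            n_nonfreezers=0,
            subject_effect_sd=0.0,
            network_offset_sd=0.0,
            roi_offset_sd=0.0,
            planted_network="Visual",
            seed=11,
        )
        spec = dataclasses.replace(
            spec, beta=planted_beta_for_r2(spec, canonical_parcellation, 0.6)
        )
        cohort = generate_cohort(spec, canonical_parcellation)
        y = np.array([s.improvement for s in cohort.subjects])
        reports = screen_networks(
            cohort.thickness,
            canonical_parcellation,
            y,
            n_null=300,
            cap=300,
            networks=["Visual", "Auditory", "Default"],
            seed=5,
        )
        assert reports[0].network == "Visual"
        assert reports[0].effect_size > 0.5
        assert all(r.effect_size < 0.5 for r in reports[1:])
        assert all(r.error is None for r in reports)

    def test_report_fields_and_exclusions(self, canonical_parcellation, default_cohort):
        y = np.array([s.improvement for s in default_cohort.subjects])
        reports = screen_networks(
            default_cohort.thickness,
            canonical_parcellation,
            y,
            n_null=50,
            cap=100,
            networks=["Salience"],
            seed=1,
        )
        (r,) = reports
        assert r.n_splits == 100 and r.n_null == 50
        assert np.isfinite(r.effect_size)
        assert 0 <= r.p_value <= 1 and 0 <= r.p_empirical <= 1
        assert 0 <= r.oos_r2 <= 1 or np.isnan(r.oos_r2)
        assert 0 <= r.first_score_r2 <= 1
        d = r.to_dict()
        assert set(d) == {
            "network", "effect_size", "p_value", "p_empirical", "oos_r2",
            "first_score_r2", "n_splits", "n_null", "passed_screen", "error",
        }

    def test_unassigned_excluded_by_default(self, canonical_parcellation):
        names = [
            n for n in canonical_parcellation.networks if n != "Unassigned"
        ]
        assert len(names) == 12
        assert "Unassigned" not in names

    def test_unknown_network_becomes_flagged_row(
        self, canonical_parcellation, default_cohort
    ):
        y = np.array([s.improvement for s in default_cohort.subjects])
        reports = screen_networks(
            default_cohort.thickness,
            canonical_parcellation,
            y,
            n_null=20,
            cap=20,
            networks=["Nope"],
            seed=1,
        )
        assert reports[0].error is not None
        assert not reports[0].passed_screen

    def test_deterministic_given_seed(self, canonical_parcellation, default_cohort):
        y = np.array([s.improvement for s in default_cohort.subjects])
        kw = dict(n_null=30, cap=50, networks=["Auditory"], seed=9)
        a = screen_networks(
            default_cohort.thickness, canonical_parcellation, y, **kw
        )
        b = screen_networks(
            default_cohort.thickness, canonical_parcellation, y, **kw
        )
        assert a[0].to_dict() == b[0].to_dict()
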