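import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from organoscore import (
    associate_cohort,
    km_estimate,
    kruskal_wallis,
    logrank,
    mann_whitney,
    mh_hazard_ratio,
    spearman,
)


def _spearman_exact_oracle(x, y):
    """Independent enumeration oracle using scipy's rho per permutation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    rho_obs = sps.spearmanr(x, y).statistic
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(sps.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
            count += 1
    return rho_obs, count / total


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman([1, 2, 3], [10, 20, 30])
        assert res.rho == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_exact_p_on_four_point_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)
        assert res.method == "exact-permutation"
        _, p_oracle = _spearman_exact_oracle([1, 2, 3, 4], [1, 3, 2, 4])
        assert p_oracle == pytest.approx(1 / 3)
        assert res.p == pytest.approx(p_oracle)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.normal(size=n)
        y = np.round(rng.normal(size=n), 1)  # rounding can induce ties
        res = spearman(x, y)
        rho_o, p_o = _spearman_exact_oracle(x, y)
        assert res.rho == pytest.approx(rho_o)
        assert res.p == pytest.approx(p_o)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        res = spearman(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "t-approximation"
        assert 0 <= res.p <= 1

    def test_errors(self):
        with pytest.raises(ValueError, match="paired"):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3 pairs"):
            spearman([1, 2], [3, 4])


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        km = km_estimate([5, 10, 15, 20], [True] * 4)
        assert km["survival"].tolist() == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert km["n_at_risk"].tolist() == [4, 3, 2, 1]

    def test_censored_subject_leaves_risk_set(self):
        km = km_estimate([5, 10, 15, 20], [True, False, True, True]).set_index("time")
        assert km.loc[5, "survival"] == pytest.approx(0.75)
        assert km.loc[15, "survival"] == pytest.approx(0.375)
        assert km.loc[20, "survival"] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([5, 10, 15], [False] * 3)
        assert (km["survival"] == 1.0).all()

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(100, 30)
        e = rng.random(30) < 0.7
        km = km_estimate(t, e)
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(50, 25), 1)
        km = km_estimate(t, np.ones(25, bool))
        for time, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((t > time).mean())

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0, 5], [True, True])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [5, 10, 15, 20]
        e = [True] * 4
        res = logrank(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_direction_early_events_in_group_one(self):
        res = logrank([1, 2, 3], [True] * 3, [10, 11, 12], [True] * 3)
        assert res.chi2 > 0
        assert res.observed1 > res.expected1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_lifelines(self, seed):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(seed)
        t1, t2 = rng.exponential(100, 15), rng.exponential(60, 12)
        e1, e2 = rng.random(15) < 0.8, rng.random(12) < 0.8
        mine = logrank(t1, e1, t2, e2)
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [True])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank([1, 2], [False, False], [3, 4], [False, False])


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        t = [5, 10, 15, 20]
        e = [True] * 4
        res = mh_hazard_ratio(t, e, t, e)
        assert res.hr == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_label_swap_inverts_hr_and_ci(self):
        rng = np.random.default_rng(0)
        t1, t2 = rng.exponential(50, 20), rng.exponential(150, 20)
        e = np.ones(20, bool)
        a = mh_hazard_ratio(t1, e, t2, e)
        b = mh_hazard_ratio(t2, e, t1, e)
        assert a.hr == pytest.approx(1 / b.hr)
        assert a.ci_low == pytest.approx(1 / b.ci_high)
        assert a.ci_high == pytest.approx(1 / b.ci_low)

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            mh_hazard_ratio([1, 2], [True, True], [3, 4], [False, False])

    def test_pike_variant_agrees_in_direction(self):
        rng = np.random.default_rng(1)
        t1, t2 = rng.exponential(40, 30), rng.exponential(120, 30)
        e = np.ones(30, bool)
        mh = mh_hazard_ratio(t1, e, t2, e)
        pike = mh_hazard_ratio(t1, e, t2, e, method="pike")
        assert mh.hr > 1 and pike.hr > 1


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_u_at_midpoint(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) * len(a) / 2)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_p_decreases_with_shift(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        other = np.array([1.5, 2.5, 3.5, 4.5])
        ps = [mann_whitney(base, other + shift)[1] for shift in (0.0, 2.0, 1000.0)]
        assert ps[0] > ps[1] >= ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        h, p = kruskal_wallis(g, g, g)
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_rank_formula(self):
        h, _ = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert h == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
        assert h == pytest.approx(4.571428, abs=1e-5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        gs = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 1)]
        h1, p1 = kruskal_wallis(*gs)
        h2, p2 = kruskal_wallis(*[np.exp(g) for g in gs])
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2], [3, 4])


class TestAssociateCohort:
    def test_positive_slope_gives_positive_rho(self, default_cohort):
        from organoscore.io import fit_stage, score_stage

        curves = fit_stage(default_cohort.viability, fit_ic50=False)
        profiles = score_stage(curves, default_cohort.clinical)
        report = associate_cohort(profiles, default_cohort.clinical)
        assert report.spearman is not None
        assert report.spearman.rho > 0
        assert report.n_overall == 40
        assert report.n_palliative == 13

    def test_all_excluded_gives_structured_empty_report(self):
        profiles = pd.DataFrame({
            "organoid": ["a", "b"], "organoid_score": [3.0, 2.0],
            "risk_class": ["high", "low"],
        })
        clinical = pd.DataFrame({
            "patient": ["a", "b"], "regimen": ["FOLFOX", "FOLFOX"],
            "pfs_days": [100.0, 200.0], "event": [True, True],
            "size_change_pct": [np.nan, np.nan], "setting": ["none", "none"],
            "exclude_bsc": [True, True],
        })
        report = associate_cohort(profiles, clinical)
        assert report.spearman is None
        assert report.logrank_overall is None
        assert report.n_overall == 0
        assert report.to_dict()["hr_overall"] is None
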