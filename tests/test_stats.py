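"""Survival and test machinery against hand/enumeration/library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cfcin import stats


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_all_events_median_by_hand(self):
        km = stats.kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3.0

    def test_all_censored_raises(self):
        with pytest.raises(ValueError):
            stats.kaplan_meier([1, 2, 3], [0, 0, 0])

    def test_mixed_six_records_product_limit_by_hand(self):
        # times 2,3,3,5,7,9 events 1,1,0,1,0,1
        # t=2: 5/6; t=3: 5/6*4/5=2/3; t=5: 2/3*2/3=4/9; t=9: 4/9*0=0
        km = stats.kaplan_meier([2, 3, 3, 5, 7, 9], [1, 1, 0, 1, 0, 1])
        assert np.allclose(km.times, [2, 3, 5, 9])
        assert np.allclose(km.survival, [5 / 6, 2 / 3, 4 / 9, 0.0])
        assert km.median == 5.0

    def test_curve_starts_at_one_and_never_increases(self, rng):
        t = rng.exponential(100, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        km = stats.kaplan_meier(t, e)
        assert km.survival_at(0.0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_median_undefined_when_curve_stays_high(self):
        km = stats.kaplan_meier([1, 2, 3, 4], [1, 0, 0, 0])
        assert math.isnan(km.median)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _grid_search_partial_likelihood(x, time, event):
    """Brute-force 1-d partial-likelihood maximizer (Breslow), oracle."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]

    def loglik(beta):
        ll = 0.0
        for i in range(len(x)):
            if event[i]:
                risk = time >= time[i]
                ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
        return ll

    grid = np.arange(-5, 5, 1e-4)
    vals = [loglik(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCox:
    def test_tiny_dataset_matches_grid_search_oracle(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        time = np.array([2.0, 3.0, 5.0, 7.0])
        event = np.array([1, 1, 1, 1])
        fit = stats.cox_ph(x[:, None], time, event)
        oracle = _grid_search_partial_likelihood(x, time, event)
        assert abs(fit.coef[0] - oracle) < 1e-4

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 300
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.01 * np.exp(0.7 * x1 - 0.3 * x2)))
        e = (t < rng.exponential(200, n)).astype(int)
        t = np.minimum(t, 1000 + rng.random(n))  # keep times distinct
        fit = stats.cox_ph(np.column_stack([x1, x2]), t, e)
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, cph.params_[["x1", "x2"]], atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_[["x1", "x2"]],
                           atol=1e-4)

    def test_null_two_group_hr_near_one(self, rng):
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(300, n)
        fit = stats.cox_ph(x[:, None], t, np.ones(n, dtype=int))
        assert 0.85 <= fit.hr[0] <= 1.18

    def test_hr_recovery_with_censoring(self, rng):
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.005 * np.exp(math.log(0.5) * x)))
        censored = rng.random(n) < 0.2
        time = np.where(censored, t * rng.random(n), t)
        fit = stats.cox_ph(x[:, None], time, (~censored).astype(int))
        assert 0.42 <= fit.hr[0] <= 0.60

    def test_monotone_likelihood_is_diagnosed(self):
        # group 1 always fails before group 0 -> diverging coefficient
        x = np.array([1.0] * 5 + [0.0] * 5)
        t = np.array([1, 2, 3, 4, 5, 10, 11, 12, 13, 14], dtype=float)
        e = np.ones(10, dtype=int)
        with pytest.raises(stats.ConvergenceError):
            stats.cox_ph(x[:, None], t, e)

    def test_constant_term_rejected(self):
        with pytest.raises(ValueError):
            stats.cox_ph(np.ones((6, 1)), np.arange(1.0, 7.0),
                         np.ones(6, dtype=int))

    def test_multivariate_reference_level_and_encoding(self, rng):
        n = 400
        df = pd.DataFrame({
            "time": rng.exponential(300, n),
            "event": np.ones(n, dtype=int),
            "group": rng.choice(["CIN-low", "CIN-high"], n),
            "age": rng.normal(65, 8, n),
            "gender": rng.choice(["male", "female"], n),
            "tnm_stage": rng.choice([2.0, 3.0, np.nan], n),
        })
        fit = stats.cox_multivariate(df, "time", "event", "group",
                                     covariates=("age", "gender", "tnm"),
                                     reference="CIN-low")
        assert fit.reference == "CIN-low"
        assert "group=CIN-high" in fit.terms
        assert "tnm_missing" in fit.terms
        assert np.all(fit.ci_lower <= fit.hr) and np.all(fit.hr <= fit.ci_upper)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _mw_enumerate(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(idx):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    lo = min(u_obs, n1 * len(b) - u_obs)
    # both tails at least as extreme as the observed U (counted once each)
    p = sum(min(u, n1 * len(b) - u) <= lo for u in us) / len(us)
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_samples_p_one(self):
        _, p = stats.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
        _, pab = stats.mann_whitney(a, b)
        _, pba = stats.mann_whitney(b, a)
        assert pab == pytest.approx(pba)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (3, 5),
                                       (4, 4), (5, 5)])
    def test_exact_path_matches_full_enumeration(self, n1, n2, rng):
        a = rng.normal(size=n1)
        b = rng.normal(0.8, 1.0, size=n2)
        u, p = stats.mann_whitney(a, b)
        u_ref, p_ref = _mw_enumerate(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_approximation_agrees_with_scipy(self, rng):
        from scipy.stats import mannwhitneyu
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1.0, size=40)
        u, p = stats.mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Spearman / AUC
# ---------------------------------------------------------------------------

class TestSpearmanAuc:
    def test_monotone_and_reversed(self):
        assert stats.spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert stats.spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_hand_rank_example(self):
        rho, _ = stats.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            stats.spearman([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import spearmanr
        x = rng.integers(0, 5, 40).astype(float)
        y = x + rng.normal(0, 2, 40)
        rho, p = stats.spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auc_pairwise_count_example(self):
        auc = stats.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_auc_extremes_and_ties(self):
        assert stats.roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert stats.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.normal(size=60) + y
        assert stats.roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40,
                    unique=True))
    def test_auc_negation_symmetry(self, scores):
        scores = np.array(scores)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a1 = stats.roc_auc(scores, labels)
        a2 = stats.roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Logistic combination
# ---------------------------------------------------------------------------

class TestCombineScores:
    def test_noise_feature_does_not_change_auc_much(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        a = y + rng.normal(0, 0.8, n)
        b = rng.normal(size=n)
        res = stats.combine_scores_logistic(a, b, y, seed=0)
        assert abs(res["auc_combined"] - res["auc_a"]) < 0.08

    def test_perfect_feature_gives_auc_one_and_flags_separation(self):
        y = np.array([0, 1] * 10)
        res = stats.combine_scores_logistic(y.astype(float),
                                            np.zeros(20) + 0.5, y, seed=0)
        assert res["auc_combined"] == 1.0
        assert res["perfect_separation"]

    def test_deterministic_under_seed(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a, b = rng.normal(size=30), rng.normal(size=30)
        r1 = stats.combine_scores_logistic(a, b, y, seed=3)
        r2 = stats.combine_scores_logistic(a, b, y, seed=3)
        assert np.array_equal(r1["combined_proba"], r2["combined_proba"])


# ---------------------------------------------------------------------------
# Binomial cohort sizing
# ---------------------------------------------------------------------------

class TestBinomialSizing:
    def test_published_cohort_sizes(self):
        assert stats.min_samples_binomial(0.1, 0.95) == 29
        assert round(stats.confidence_at_n(0.1, 24) * 100) == 92

    def test_degenerate_and_small_cases(self):
        assert stats.min_samples_binomial(1.0, 0.9) == 1
        assert stats.min_samples_binomial(0.5, 0.95) == 5
        assert stats.confidence_at_n(0.1, 0) == 0.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            stats.min_samples_binomial(0.0, 0.95)

    @given(st.floats(0.01, 0.99), st.floats(0.5, 0.999))
    def test_min_samples_consistent_with_confidence(self, p, c):
        n = stats.min_samples_binomial(p, c)
        assert stats.confidence_at_n(p, n) >= c
        if n > 1:
            assert stats.confidence_at_n(p, n - 1) < c


def test_significance_star_convention():
    assert stats.significance_stars(0.03) == "*"
    assert stats.significance_stars(0.0009) == "***"
    assert stats.significance_stars(0.5) == "ns"
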