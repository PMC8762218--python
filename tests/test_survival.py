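import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from m6apattern import cox_fit, km_fit, logrank_test, optimal_cutpoint, survival_by_groups, td_auc
from m6apattern.survival import DAYS_PER_YEAR, partial_log_likelihood


def _sim_surv(rng, n, beta=0.0, censor_scale=2.0):
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(censor_scale, size=n)
    return x, np.minimum(t, c) + 1e-9, (t <= c).astype(int)


class TestKmFit:
    def test_all_censored_identity(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_fit([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at([0.5, 2.5, 10.0]).tolist() == [1.0, 1.0, 1.0]

    def test_hand_product_limit(self):
        km = km_fit([1, 2, 3, 4], [1, 1, 0, 1])
        np.testing.assert_allclose(km.survival, [3 / 4, 1 / 2, 0.0])
        np.testing.assert_allclose(km.at_risk, [4, 3, 1])
        np.testing.assert_allclose(km.events, [1, 1, 1])

    def test_step_heights_are_d_over_n(self):
        rng = np.random.default_rng(0)
        _, t, e = _sim_surv(rng, 40)
        km = km_fit(t, e)
        prev = np.concatenate([[1.0], km.survival[:-1]])
        np.testing.assert_allclose(km.survival, prev * (1 - km.events / km.at_risk))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        _, t, e = _sim_surv(rng, 100)
        km = km_fit(t, e)
        lf = KaplanMeierFitter().fit(t, e)
        ours = km.survival_at(km.event_times)
        theirs = lf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_time_rescale_invariance(self):
        rng = np.random.default_rng(2)
        _, t, e = _sim_surv(rng, 60)
        a = km_fit(t, e)
        b = km_fit(t * 30.4, e)  # days -> months-ish
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.event_times * 30.4, b.event_times)


def hand_logrank_two_groups(time, event, group):
    """Oracle: enumerate the 2x2 table at each distinct event time."""
    time, event, group = map(np.asarray, (time, event, group))
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_subject_hypergeometric_oracle(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 1]
        g = [0, 1, 0]
        res = logrank_test(t, e, g)
        expected = hand_logrank_two_groups(t, e, np.array(g))
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            _, t, e = _sim_surv(rng, 25)
            g = rng.integers(0, 2, size=25)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            res = logrank_test(t, e, g)
            assert res.statistic == pytest.approx(hand_logrank_two_groups(t, e, g), abs=1e-10)

    def test_matches_lifelines_multigroup(self):
        rng = np.random.default_rng(4)
        _, t, e = _sim_surv(rng, 90)
        g = rng.integers(0, 3, size=90)
        res = logrank_test(t, e, g)
        lf = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(lf.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(lf.p_value, rel=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCoxFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        x, t, e = _sim_surv(rng, 500, beta=0.7)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert fit.converged
        assert fit.summary.loc["x", "beta"] == pytest.approx(0.7, abs=0.2)

    def test_ci_coverage_null(self):
        rng = np.random.default_rng(6)
        covered = 0
        reps = 40
        for _ in range(reps):
            x, t, e = _sim_surv(rng, 120, beta=0.0)
            fit = cox_fit(t, e, pd.DataFrame({"x": x}))
            lo = fit.summary.loc["x", "beta"] - 1.96 * fit.summary.loc["x", "se"]
            hi = fit.summary.loc["x", "beta"] + 1.96 * fit.summary.loc["x", "se"]
            covered += lo <= 0 <= hi
        assert covered / reps >= 0.85

    def test_tie_free_efron_equals_breslow(self):
        rng = np.random.default_rng(7)
        x, t, e = _sim_surv(rng, 50, beta=0.5)
        assert len(np.unique(t)) == 50  # tie-free
        for beta in (-0.3, 0.0, 0.8):
            a = partial_log_likelihood(t, e, x, beta, ties="efron")
            b = partial_log_likelihood(t, e, x, beta, ties="breslow")
            assert a == pytest.approx(b, abs=1e-10)

    def test_loglik_at_fitted_beta_maximal(self):
        rng = np.random.default_rng(8)
        x, t, e = _sim_surv(rng, 150, beta=0.6)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        b = fit.summary.loc["x", "beta"]
        ll_hat = partial_log_likelihood(t, e, x, b)
        for db in (-0.05, 0.05):
            assert partial_log_likelihood(t, e, x, b + db) < ll_hat

    def test_ci_definition(self):
        rng = np.random.default_rng(9)
        x, t, e = _sim_surv(rng, 80, beta=0.4)
        fit = cox_fit(t, e, pd.DataFrame({"x": x}))
        row = fit.summary.loc["x"]
        assert row["ci_lo"] == pytest.approx(np.exp(row["beta"] - 1.96 * row["se"]))
        assert row["ci_hi"] == pytest.approx(np.exp(row["beta"] + 1.96 * row["se"]))
        assert row["hr"] > 0

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1], pd.DataFrame({"x": [1.0] * 4}))


class TestOptimalCutpoint:
    def test_perfect_regime_separation(self):
        rng = np.random.default_rng(10)
        n = 120
        marker = np.sort(rng.uniform(0, 10, size=n))
        fast = marker > 5.0  # high marker -> high hazard
        t = np.where(fast, rng.exponential(0.3, n), rng.exponential(3.0, n)) + 1e-9
        e = np.ones(n, dtype=int)
        below = marker[marker <= 5.0]
        res = optimal_cutpoint(marker, t, e)
        assert below.max() - 1.0 < res.cutoff <= 5.0
        assert res.n_low + res.n_high == n

    def test_minprop_respected(self):
        rng = np.random.default_rng(11)
        _, t, e = _sim_surv(rng, 60)
        marker = rng.normal(size=60)
        res = optimal_cutpoint(marker, t, e, minprop=0.2)
        assert res.n_low >= int(np.ceil(0.2 * 60))
        assert res.n_high >= int(np.ceil(0.2 * 60))

    def test_noise_marker_cutoff_varies_and_naive_p_anticonservative(self):
        rng = np.random.default_rng(12)
        cutoffs, naive_ps = [], []
        for _ in range(15):
            x, t, e = _sim_surv(rng, 80)
            marker = rng.normal(size=80)
            res = optimal_cutpoint(marker, t, e)
            cutoffs.append(res.cutoff)
            naive_ps.append(res.p_naive)
        assert len(set(np.round(cutoffs, 6))) > 5
        # naive p ignores selection: strongly sub-uniform under the null
        assert np.mean(np.array(naive_ps) < 0.05) > 0.15

    def test_permutation_p_calibrated_vs_naive(self):
        rng = np.random.default_rng(13)
        x, t, e = _sim_surv(rng, 70)
        marker = rng.normal(size=70)
        res = optimal_cutpoint(marker, t, e, n_permutations=60, seed=1)
        assert res.p_permutation is not None
        assert res.p_permutation >= res.p_naive

    def test_no_admissible_cutoff(self):
        with pytest.raises(ValueError, match="admissible"):
            optimal_cutpoint([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])


def brute_force_auc(marker, time, event, horizon):
    """Censoring-free oracle: concordant case/control pair fraction."""
    cases = [i for i in range(len(time)) if time[i] <= horizon and event[i] == 1]
    controls = [j for j in range(len(time)) if time[j] > horizon]
    num = sum(
        1.0 if marker[i] > marker[j] else 0.5 if marker[i] == marker[j] else 0.0
        for i in cases
        for j in controls
    )
    return num / (len(cases) * len(controls))


class TestTdAuc:
    def test_perfect_anti_risk_marker(self):
        n = 30
        t = np.arange(1, n + 1, dtype=float)
        e = np.ones(n, dtype=int)
        marker = t.copy()  # larger marker = later event = lower risk
        res = td_auc(marker, t, e, horizons_years=[10 / DAYS_PER_YEAR], orient=False)
        assert list(res.auc.values())[0] == pytest.approx(0.0)
        res2 = td_auc(marker, t, e, horizons_years=[10 / DAYS_PER_YEAR], orient=True)
        assert list(res2.auc.values())[0] == pytest.approx(1.0)
        assert res2.flipped

    def test_censoring_free_matches_combinatorial_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            n = 25
            marker = rng.normal(size=n)
            t = rng.exponential(2.0, size=n) + 0.01
            e = np.ones(n, dtype=int)
            horizon = np.median(t)
            res = td_auc(marker, t, e, horizons_years=[horizon / DAYS_PER_YEAR])
            expected = brute_force_auc(marker, t, e, horizon)
            assert list(res.auc.values())[0] == pytest.approx(expected, abs=1e-12)

    def test_horizon_beyond_followup_dropped(self):
        rng = np.random.default_rng(15)
        _, t, e = _sim_surv(rng, 50)
        horizons = [np.median(t) / DAYS_PER_YEAR, t.max() / DAYS_PER_YEAR + 1]
        with pytest.warns(UserWarning, match="dropped"):
            res = td_auc(np.arange(50.0), t, e, horizons_years=horizons)
        assert len(res.dropped_horizons) == 1
        assert len(res.auc) == 1

    def test_null_marker_mean_half(self):
        rng = np.random.default_rng(16)
        aucs = []
        for _ in range(60):
            x, t, e = _sim_surv(rng, 100)
            marker = rng.normal(size=100)
            res = td_auc(marker, t, e, horizons_years=[np.median(t) / DAYS_PER_YEAR])
            aucs.append(list(res.auc.values())[0])
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_auc_bounds(self):
        rng = np.random.default_rng(17)
        x, t, e = _sim_surv(rng, 80, beta=1.0)
        res = td_auc(-x, t, e, horizons_years=[np.median(t) / DAYS_PER_YEAR])
        for a in res.auc.values():
            assert 0.0 <= a <= 1.0


class TestSurvivalByGroups:
    def test_identical_groups_global_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = survival_by_groups(t, e, g)
        assert res["global"].p_value == pytest.approx(1.0)

    def test_pairwise_count(self):
        rng = np.random.default_rng(18)
        _, t, e = _sim_surv(rng, 90)
        g = rng.choice(list("abcd"), size=90)
        res = survival_by_groups(t, e, g)
        assert len(res["pairwise"]) == 4 * 3 // 2

    def test_planted_poor_cluster_lowest_survival(self, planted_cohort):
        clin = planted_cohort.clinical
        res = survival_by_groups(clin.os_time, clin.os_event, planted_cohort.truth["cluster"])
        med = np.median(clin.os_time)
        s = {g: c.survival_at([med])[0] for g, c in res["curves"].items()}
        assert s["B"] == min(s.values())  # cluster B = high latent = high hazard
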