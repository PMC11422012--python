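"""Survival machinery and categorical-response statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chemosig as cs
from chemosig.clinical import (
    ClinicalCohort,
    best_cutpoint,
    chi_square,
    combine_drug_labels,
    cox_fit,
    iptw_adjusted_km,
    km_estimate,
    lausen_schumacher_p,
    logrank_test,
    orr_exact,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def oracle_logrank_two_group(times, events, group):
    """Risk-table log-rank recomputed from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events])):
        at = times >= t
        d = float((events & (times == t)).sum())
        d1 = float((events & (times == t) & group).sum())
        n = float(at.sum())
        n1 = float((at & group).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O1 - E1) ** 2 / V
    return chi2, stats.chi2.sf(chi2, 1)


def oracle_efron_loglik(beta, x, times, events):
    """Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    eta = beta * np.asarray(x, float)
    r = np.exp(eta)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    for t in sorted(set(times[events])):
        D = np.flatnonzero(events & (times == t))
        R = np.flatnonzero(times >= t)
        sum_r = r[R].sum()
        sum_rd = r[D].sum()
        d = len(D)
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_rd)
    return ll


# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_flat_curve_median_not_reached(self):
        km = km_estimate([3, 5, 8], [False, False, False])
        assert np.all(km.survival == 1.0)
        assert np.isnan(km.median)
        assert km.median_label == "not reached"

    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [True, True, True, True])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0
        assert np.allclose(km.at_risk, [4, 3, 2, 1])

    def test_all_events_untied_gives_exact_fractions(self, rng):
        t = np.sort(rng.uniform(1, 100, 25))
        km = km_estimate(t, np.ones(25, bool))
        n = 25
        assert np.allclose(km.survival, [(n - i) / n for i in range(1, n + 1)])

    def test_duplicated_dataset_identical_curve(self, rng):
        t = rng.uniform(1, 50, 30)
        e = rng.random(30) < 0.7
        km1 = km_estimate(t, e)
        km2 = km_estimate(np.concatenate([t, t]), np.concatenate([e, e]))
        assert np.allclose(km1.times, km2.times)
        assert np.allclose(km1.survival, km2.survival)

    def test_unit_weights_equal_unweighted(self, rng):
        t = rng.uniform(1, 50, 40)
        e = rng.random(40) < 0.6
        km1 = km_estimate(t, e)
        km2 = km_estimate(t, e, weights=np.ones(40))
        assert np.allclose(km1.survival, km2.survival)

    def test_greenwood_se_positive_after_first_event(self):
        km = km_estimate([1, 2, 3, 4, 5], [True, True, False, True, False])
        assert np.all(km.greenwood_se[:-1] >= 0)


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [True] * 8
        g = [0] * 4 + [1] * 4
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_small_case_matches_brute_force(self):
        t = [1, 2, 3, 4]
        e = [True] * 4
        g = [True, True, False, False]
        chi2, df, p = logrank_test(t, e, g)
        c2, p2 = oracle_logrank_two_group(t, e, g)
        assert chi2 == pytest.approx(c2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_data_matches_brute_force_and_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.random(40) < 0.7
        g = rng.random(40) < 0.5
        if not e.any():
            return
        chi2, _, p = logrank_test(t, e, g)
        c2, _ = oracle_logrank_two_group(t, e, g)
        assert chi2 == pytest.approx(c2, abs=1e-10)
        from lifelines.statistics import logrank_test as ll_logrank
        ll = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ll.test_statistic, abs=1e-8)

    def test_three_groups_df_two(self, rng):
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.8
        g = rng.integers(0, 3, 60)
        chi2, df, p = logrank_test(t, e, g)
        assert df == 2 and chi2 >= 0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [True, True], ["a", "a"])

    def test_null_p_uniform_under_label_permutation(self):
        """Group labels permuted on fixed survival data: p ~ U(0,1)."""
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.8
        ps = []
        for _ in range(500):
            g = rng.permutation(np.repeat([0, 1], 20))
            ps.append(logrank_test(t, e, g)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBestCutpoint:
    def test_constructed_separation_found(self, rng):
        scores = pd.Series(np.arange(1.0, 21.0), index=[f"p{i}" for i in range(20)])
        times = np.where(scores > 10, rng.uniform(50, 60, 20), rng.uniform(5, 6, 20))
        res = best_cutpoint(scores, times, np.ones(20, bool), n_permutations=0)
        assert 10 < res.cutpoint < 11
        assert res.labels.sum() == 10
        assert res.logrank_p < 1e-4

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            best_cutpoint(pd.Series(np.ones(12)), np.arange(1.0, 13.0), np.ones(12, bool))

    def test_reported_p_matches_logrank_at_cutpoint(self, rng):
        scores = pd.Series(rng.normal(size=30))
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.8
        res = best_cutpoint(scores, t, e, n_permutations=0)
        chi2, _, p = logrank_test(t, e, (scores > res.cutpoint).to_numpy())
        assert res.logrank_chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.logrank_p == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = pd.Series(rng.normal(size=n).round(2))
        if scores.nunique() < 2:
            return
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.8
        res = best_cutpoint(scores, t, e, n_permutations=0)
        # oracle: brute-force every admissible midpoint with logrank_test
        distinct = np.unique(scores)
        best = None
        min_n = int(np.ceil(0.1 * n))
        for c in (distinct[:-1] + distinct[1:]) / 2:
            hi = scores.to_numpy() > c
            if hi.sum() < min_n or (n - hi.sum()) < min_n:
                continue
            _, _, p = logrank_test(t, e, hi)
            key = (p, -min(hi.sum(), n - hi.sum()), c)
            if best is None or key < best:
                best = key
        assert res.cutpoint == pytest.approx(best[2])
        assert res.logrank_p == pytest.approx(best[0], abs=1e-12)

    def test_no_admissible_cutpoint_rejected(self):
        # one outlier score: every split strands fewer than 20% on one side
        scores = pd.Series([1.0] * 11 + [9.0])
        with pytest.raises(ValueError, match="no cutpoint"):
            best_cutpoint(scores, np.arange(1.0, 13.0), np.ones(12, bool),
                          min_group_proportion=0.2)

    def test_permutation_adjusted_p_is_calibrated(self):
        """Null scores: adjusted p < 0.05 in roughly 5% of datasets,
        while the raw minimum p is inflated far beyond its nominal level."""
        rng = np.random.default_rng(3)
        raw_hits = adj_hits = reps = 0
        for _ in range(60):
            n = 60
            scores = pd.Series(rng.normal(size=n))
            t = rng.exponential(10, n)
            e = rng.random(n) < 0.85
            res = best_cutpoint(scores, t, e, n_permutations=99, permutation_seed=1)
            reps += 1
            raw_hits += res.logrank_p < 0.05
            adj_hits += res.p_adjusted < 0.05
        assert adj_hits / reps < 0.15
        assert raw_hits / reps > 0.25  # why the adjustment exists

    def test_lausen_schumacher_monotone_and_bounded(self):
        ps = [lausen_schumacher_p(c, 0.1) for c in (0.5, 2, 5, 10, 20)]
        assert all(0 <= p <= 1 for p in ps)
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.array([3.0, 5, 8, 12, 3, 5, 8, 12])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1], bool)
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        res = cox_fit(pd.DataFrame({"g": x}), t, e)
        assert res.loc["g", "hr"] == pytest.approx(1.0, abs=1e-8)

    def test_label_swap_reciprocal_symmetry(self, rng):
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.8
        x = (rng.random(50) < 0.5).astype(float)
        hr = cox_fit(pd.DataFrame({"g": x}), t, e).loc["g", "hr"]
        hr_swapped = cox_fit(pd.DataFrame({"g": 1 - x}), t, e).loc["g", "hr"]
        assert hr * hr_swapped == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_newton_matches_grid_search_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.where(x == 1, 5.0, 12.0))
        e = rng.random(n) < 0.85
        if e.sum() < 5:
            return
        beta_hat = np.log(cox_fit(pd.DataFrame({"g": x}), t, e).loc["g", "hr"])
        # golden-section refinement of the Efron partial likelihood
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda b: -oracle_efron_loglik(b, x, t, e),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert beta_hat == pytest.approx(res.x, abs=1e-6)

    def test_wald_ci_structure(self, rng):
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.8
        x = (rng.random(80) < 0.5).astype(float)
        row = cox_fit(pd.DataFrame({"g": x}), t, e).loc["g"]
        assert row["ci_low"] == pytest.approx(np.exp(row["beta"] - 1.959963984540054 * row["se"]))
        assert row["ci_high"] == pytest.approx(np.exp(row["beta"] + 1.959963984540054 * row["se"]))

    def test_separation_detected(self):
        # covariate perfectly orders survival: monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, bool)
        x = (t > 10).astype(float)
        with pytest.raises(ValueError, match="separation|identifiable"):
            cox_fit(pd.DataFrame({"g": x}), t, e)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"g": np.ones(10)}), np.arange(1.0, 11.0), np.ones(10, bool))

    def test_more_covariates_than_events_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [0.0, 1, 0, 1], "c": [5.0, 1, 2, 8]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, [1.0, 2, 3, 4], [True, False, False, True])


class TestIPTW:
    def test_no_confounding_weights_near_one(self):
        rng = np.random.default_rng(0)
        n = 500
        x = rng.normal(size=n)
        g = rng.random(n) < 0.5  # independent of x
        t = rng.exponential(10, n)
        e = rng.random(n) < 0.8
        out = iptw_adjusted_km(np.where(g, "A", "B"), t, e, pd.DataFrame({"x": x}))
        assert np.abs(out["weights"].to_numpy() - 1).mean() < 0.1
        for lab in ("A", "B"):
            grid = np.linspace(0.5, 30, 40)
            w = np.array([out[lab]["weighted"].survival_at(u) for u in grid])
            u_ = np.array([out[lab]["unweighted"].survival_at(u) for u in grid])
            assert np.abs(w - u_).max() < 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_confounder_adjustment_moves_toward_truth(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        x = rng.normal(size=n)
        g = rng.random(n) < stats.norm.cdf(1.5 * x)
        t = rng.exponential(1 / (0.1 * np.exp(0.8 * x)))
        c = rng.uniform(5, 50, n)
        tt, e = np.minimum(t, c), t <= c
        out = iptw_adjusted_km(np.where(g, "A", "B"), tt, e, pd.DataFrame({"x": x}))
        rng2 = np.random.default_rng(1000 + seed)
        x_big = rng2.normal(size=20000)
        t_true = rng2.exponential(1 / (0.1 * np.exp(0.8 * x_big)))
        grid = np.linspace(0.1, 30, 50)
        S_true = np.array([(t_true > u).mean() for u in grid])

        def supnorm(curve):
            return np.abs(np.array([curve.survival_at(u) for u in grid]) - S_true).max()

        adj = max(supnorm(out["A"]["weighted"]), supnorm(out["B"]["weighted"]))
        unadj = max(supnorm(out["A"]["unweighted"]), supnorm(out["B"]["unweighted"]))
        assert adj < unadj

    def test_perfect_separation_rejected(self):
        x = np.array([-3.0] * 10 + [3.0] * 10) * 100
        g = x > 0
        with pytest.raises(ValueError, match="propensity|separation"):
            iptw_adjusted_km(np.where(g, "A", "B"), np.arange(1.0, 21.0),
                             np.ones(20, bool), pd.DataFrame({"x": x}))


class TestCombination:
    def _strat(self, labels):
        idx = [f"p{i}" for i in range(len(labels))]
        km = km_estimate([1.0], [True])
        return cs.StratificationResult(
            cutpoint=0.0, labels=pd.Series(labels, index=idx), logrank_chi2=0.0,
            logrank_p=1.0, p_adjusted=1.0, n_candidates=1, km_positive=km,
            km_negative=km, hr=1.0, hr_ci=(0.5, 2.0), hr_p=1.0,
        )

    def test_counts(self):
        prof = combine_drug_labels({
            "5FU": self._strat([True, True, False]),
            "oxaliplatin": self._strat([False, True, False]),
            "irinotecan": self._strat([True, True, False]),
        })
        assert prof.sensitive_count.tolist() == [2, 3, 0]
        assert prof.counts_table().loc[3] == 1

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            combine_drug_labels({
                "a": self._strat([True, False]),
                "b": self._strat([True, False, True]),
            })


class TestORR:
    def test_zero_responders_closed_form(self):
        orr, lo, hi, p = orr_exact(["SD"] * 5 + ["PD"] * 5, p0=0.3)
        assert orr == 0.0 and lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_responders_upper_bound_one(self):
        orr, lo, hi, _ = orr_exact(["PR"] * 8)
        assert orr == 1.0 and hi == 1.0

    def test_half_responders_symmetric_beta_oracle(self):
        orr, lo, hi, _ = orr_exact(["CR"] * 5 + ["PD"] * 5)
        assert orr == 0.5
        assert lo == pytest.approx(stats.beta.ppf(0.025, 5, 6))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 6, 5))
        assert lo + hi == pytest.approx(1.0, abs=1e-10)  # symmetry at k = n/2

    def test_ci_contains_estimate_and_narrows_with_n(self):
        for k, n in [(2, 10), (7, 20), (15, 40)]:
            resp = ["PR"] * k + ["PD"] * (n - k)
            orr, lo, hi, _ = orr_exact(resp)
            assert lo <= orr <= hi
        w_small = np.subtract(*orr_exact(["PR"] * 3 + ["PD"] * 7)[2:0:-1]) * -1
        w_big = np.subtract(*orr_exact(["PR"] * 30 + ["PD"] * 70)[2:0:-1]) * -1
        assert abs(w_big) < abs(w_small)

    def test_p_value_is_exact_binomial(self):
        _, _, _, p = orr_exact(["PR"] * 3 + ["PD"] * 7, p0=0.5)
        assert p == pytest.approx(stats.binomtest(3, 10, 0.5).pvalue)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            orr_exact([])
        with pytest.raises(ValueError):
            orr_exact(["PR"], p0=1.5)
        with pytest.raises(ValueError):
            orr_exact(["WEIRD"])


class TestChiSquare:
    def test_balanced_table_zero(self):
        chi2, df, p = chi_square([[50, 50], [50, 50]])
        assert chi2 == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, df, _ = chi_square([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(4 * 25 / 15)
        assert df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_rxc_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(5, 50, size=(3, 4)).astype(float)
        chi2, df, _ = chi_square(obs)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        expected = row @ col / obs.sum()
        assert chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum(), abs=1e-10)
        assert df == 6

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 3]])


class TestClinicalCohort:
    def test_required_columns_enforced(self):
        with pytest.raises(ValueError, match="os_time"):
            ClinicalCohort(pd.DataFrame({"id": ["a"], "arm": ["mFFX"]}))

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"id": ["a", "a"], "arm": ["mFFX"] * 2,
                           "os_time": [1.0, 2.0], "os_event": [True, False]})
        with pytest.raises(ValueError, match="duplicate"):
            ClinicalCohort(df)

    def test_nonpositive_times_rejected(self):
        df = pd.DataFrame({"id": ["a"], "arm": ["mFFX"], "os_time": [0.0],
                           "os_event": [True]})
        with pytest.raises(ValueError, match="> 0"):
            ClinicalCohort(df)

    def test_arm_subset(self):
        df = pd.DataFrame({"id": list("abc"), "arm": ["mFFX", "GEM", "mFFX"],
                           "os_time": [1.0, 2.0, 3.0], "os_event": [True] * 3})
        sub = ClinicalCohort(df).arm_subset("mFFX")
        assert sub.n_patients == 2
        with pytest.raises(ValueError):
            ClinicalCohort(df).arm_subset("nope")
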