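import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gemana.evaluation import (
    EvaluationError,
    brier_90d,
    compare_c_one_shot,
    cox_predicted_risk,
    decision_curve,
    evaluate_scores,
    gnd_calibration,
    harrell_c,
    ipcw_brier,
    km_event_prob,
    reclassify,
)
from tests.conftest import brute_force_c


class TestHarrellC:
    def test_perfect_concordance(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.ones(5, bool)
        s = np.array([50.0, 40.0, 30.0, 20.0, 10.0])  # higher score fails first
        assert harrell_c(s, t, e).c == 1.0

    def test_constant_score_is_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        assert harrell_c(np.ones(4), t, e).c == 0.5

    def test_six_patient_mixed_censoring_vs_brute_force(self):
        t = np.array([2.0, 5.0, 5.0, 9.0, 12.0, 90.0])
        e = np.array([1, 1, 0, 1, 0, 0], bool)
        s = np.array([22.0, 18.0, 18.0, 25.0, 10.0, 8.0])
        res = harrell_c(s, t, e)
        assert res.c == pytest.approx(brute_force_c(s, t, e), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        t = rng.integers(1, 25, n).astype(float)
        e = rng.random(n) < 0.6
        s = rng.integers(6, 18, n).astype(float)
        oracle = brute_force_c(s, t, e)
        if oracle is None:
            with pytest.raises(EvaluationError):
                harrell_c(s, t, e)
        else:
            assert harrell_c(s, t, e).c == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_scikit_survival_when_tie_free(self, rng):
        """On tie-free data every usability convention coincides, so an
        independent library must give the same c."""
        from sksurv.metrics import concordance_index_censored

        n = 300
        t = rng.random(n) * 90 + 0.01
        e = rng.random(n) < 0.4
        s = rng.standard_normal(n)
        ours = harrell_c(s, t, e).c
        theirs = concordance_index_censored(e, t, s)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_ci_contains_point(self, small_cohort_frame):
        df = small_cohort_frame
        res = harrell_c(df["gema_na_cont"], df["time"], df["event"])
        assert res.ci_lower <= res.c <= res.ci_upper
        assert 0 < res.se < 0.2

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            harrell_c([1.0, 2.0], [90.0, 90.0], [False, False])


class TestCompareOneShot:
    def test_self_comparison_convention(self, rng):
        t = rng.integers(1, 91, 100).astype(float)
        e = rng.random(100) < 0.4
        s = rng.standard_normal(100)
        res = compare_c_one_shot(s, s, t, e)
        assert (res.difference, res.variance, res.p_value) == (0.0, 0.0, 1.0)

    def test_variance_nonnegative_and_symmetric(self, rng):
        t = rng.integers(1, 91, 200).astype(float)
        e = rng.random(200) < 0.4
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        ab = compare_c_one_shot(a, b, t, e)
        ba = compare_c_one_shot(b, a, t, e)
        assert ab.variance >= 0
        assert ab.difference == pytest.approx(-ba.difference)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_variance_close_to_jackknife(self, rng):
        """The one-shot influence-component variance should approximate the
        leave-one-out jackknife variance of the c difference."""
        n = 100
        L = rng.standard_normal(n)
        a = L + 0.7 * rng.standard_normal(n)
        b = L + 0.7 * rng.standard_normal(n)
        lam = 0.004 * np.exp(0.8 * L)
        t = np.ceil(np.minimum(np.minimum(rng.exponential(1 / lam),
                                          rng.exponential(1 / 0.015, n)), 90.0))
        e = (t < 90) & (rng.random(n) < 0.9)
        res = compare_c_one_shot(a, b, t, e)
        loo = []
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            loo.append(harrell_c(a[m], t[m], e[m]).c
                       - harrell_c(b[m], t[m], e[m]).c)
        loo = np.asarray(loo)
        jack = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert res.variance == pytest.approx(jack, rel=0.15)

    def test_detects_real_difference(self, small_cohort_frame):
        df = small_cohort_frame
        noisy = df["gema_na_cont"] + np.random.default_rng(0).normal(0, 12, len(df))
        res = compare_c_one_shot(df["gema_na_cont"], noisy,
                                 df["time"], df["event"])
        assert res.difference > 0 and res.p_value < 0.05


class TestBrier:
    def test_perfect_forecast_is_zero(self):
        t = np.array([10.0, 20.0, 90.0, 90.0])
        e = np.array([1, 1, 0, 0], bool)
        p = np.array([1.0, 1.0, 0.0, 0.0])
        assert ipcw_brier(p, t, e) == 0.0

    def test_climatological_forecast_closed_form(self):
        """Uncensored, constant forecast p with event rate p gives p(1-p)."""
        n, k = 100, 30
        t = np.concatenate([np.linspace(1, 80, k), np.full(n - k, 90.0)])
        e = np.concatenate([np.ones(k, bool), np.zeros(n - k, bool)])
        p = np.full(n, k / n)
        assert ipcw_brier(p, t, e) == pytest.approx(0.3 * 0.7, abs=1e-12)

    def test_noisier_score_scores_worse(self, small_cohort_frame):
        df = small_cohort_frame
        rng = np.random.default_rng(1)
        clean = brier_90d(df["gema_na_cont"], df["time"], df["event"])
        noisy = brier_90d(df["gema_na_cont"] + rng.normal(0, 15, len(df)),
                          df["time"], df["event"])
        assert clean < noisy

    def test_cox_risk_mapping_is_monotone(self, small_cohort_frame):
        df = small_cohort_frame.sort_values("gema_na_cont")
        risk = cox_predicted_risk(df["gema_na_cont"], df["time"], df["event"])
        assert np.all(np.diff(risk) >= -1e-12)
        assert np.all((risk >= 0) & (risk <= 1))


class TestGnd:
    def test_two_bin_hand_example(self):
        """Two externally defined risk strata, censoring in each; the
        chi-square is recomputed from closed-form product-limit values."""
        # low bin: 10 patients, events at 10 and 20, censor at 30
        t_lo = np.array([10.0, 20.0, 30.0] + [90.0] * 7)
        e_lo = np.array([1, 1, 0] + [0] * 7, bool)
        # high bin: 10 patients, events at 5, 15, 40, 40, censor at 25
        t_hi = np.array([5.0, 15.0, 25.0, 40.0, 40.0] + [90.0] * 5)
        e_hi = np.array([1, 1, 0, 1, 1] + [0] * 5, bool)
        p = np.concatenate([np.full(10, 0.25), np.full(10, 0.45)])
        t = np.concatenate([t_lo, t_hi])
        e = np.concatenate([e_lo, e_hi])

        def hand_km(ts, es):
            surv, var_sum = 1.0, 0.0
            n = len(ts)
            order = np.argsort(ts)
            at_risk = n
            for u in np.unique(ts):
                d = int(np.sum((ts == u) & es))
                r = int(np.sum(ts >= u))
                if d:
                    surv *= 1 - d / r
                    var_sum += d / (r * (r - d))
            return 1 - surv, surv ** 2 * var_sum

        obs_lo, var_lo = hand_km(t_lo, e_lo)
        obs_hi, var_hi = hand_km(t_hi, e_hi)
        expect = ((obs_lo - 0.25) ** 2 / var_lo + (obs_hi - 0.45) ** 2 / var_hi)
        res = gnd_calibration(p, t, e, n_bins=2)
        assert res.status == "ok"
        assert res.chi2 == pytest.approx(expect, abs=1e-9)
        assert res.df == 2
        assert res.observed_prob == pytest.approx([obs_lo, obs_hi], abs=1e-12)

    def test_identical_risks_not_assessable(self):
        t = np.linspace(1, 90, 50)
        e = np.tile([True, False], 25)
        res = gnd_calibration(np.full(50, 0.3), t, e)
        assert res.status == "not_assessable"

    def test_sparse_deciles_merged_until_rule_holds(self, rng):
        n = 2000
        # bottom deciles get nearly zero predicted risk -> must merge
        p = np.concatenate([np.full(n // 2, 0.001),
                            rng.uniform(0.05, 0.6, n - n // 2)])
        lam = -np.log(1 - np.clip(p, 1e-6, 0.99)) / 90
        t = np.ceil(np.minimum(rng.exponential(1 / lam), 90.0))
        e = t < 90
        res = gnd_calibration(p, t, e)
        assert res.status in ("ok", "not_assessable")
        if res.status == "ok":
            assert np.all(res.expected_events >= 2.0)
            assert len(res.merge_trace) > 0
        # the merge map must partition the original deciles contiguously
        assert sorted(set(res.bin_of_decile)) == list(range(max(res.bin_of_decile) + 1))
        assert np.all(np.diff(res.bin_of_decile) >= 0)

    def test_df_conventions(self, rng):
        n = 3000
        p = rng.uniform(0.05, 0.6, n)
        lam = -np.log(1 - p) / 90
        t = np.ceil(np.minimum(rng.exponential(1 / lam), 90.0))
        e = t < 90
        res_k = gnd_calibration(p, t, e, df_convention="bins")
        res_k1 = gnd_calibration(p, t, e, df_convention="bins_minus_1")
        assert res_k.chi2 == pytest.approx(res_k1.chi2)
        assert res_k.df == res_k1.df + 1

    def test_out_of_range_risks_rejected(self):
        with pytest.raises(EvaluationError):
            gnd_calibration([0.2, 1.3], [10, 20], [True, False])


class TestDecisionCurve:
    def test_treat_none_is_zero(self, small_cohort_frame):
        df = small_cohort_frame
        risk = cox_predicted_risk(df["gema_na_cont"], df["time"], df["event"])
        dc = decision_curve(risk, df["time"], df["event"])
        assert np.all(dc.treat_none == 0.0)

    def test_treat_all_limit_at_small_threshold(self):
        t = np.concatenate([np.linspace(1, 60, 20), np.full(80, 90.0)])
        e = np.concatenate([np.ones(20, bool), np.zeros(80, bool)])
        risk = np.where(e, 0.9, 0.1)
        dc = decision_curve(risk, t, e, thresholds=[0.001])
        overall = km_event_prob(t, e)[0]
        assert dc.treat_all[0] == pytest.approx(overall, abs=1e-3)

    def test_perfect_separation_dominates(self):
        t = np.concatenate([np.linspace(1, 60, 20), np.full(80, 90.0)])
        e = np.concatenate([np.ones(20, bool), np.zeros(80, bool)])
        risk = np.where(e, 0.95, 0.02)
        dc = decision_curve(risk, t, e, thresholds=np.arange(0.05, 0.9, 0.05))
        assert np.all(dc.net_benefit >= dc.treat_all - 1e-12)
        assert np.all(dc.net_benefit >= -1e-12)

    def test_empty_subset_flagged(self):
        t = np.array([10.0, 90.0])
        e = np.array([True, False])
        dc = decision_curve(np.array([0.1, 0.1]), t, e, thresholds=[0.5])
        assert dc.net_benefit[0] == 0.0
        assert dc.empty_thresholds == (0.5,)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(EvaluationError):
            decision_curve([0.2], [10.0], [True], thresholds=[1.5])


class TestReclassify:
    def test_identity_is_all_diagonal_unchanged(self):
        a = np.array([8, 12, 15, 20])
        res = reclassify(a, a, [0, 1, 0, 0], [1, 0, 0, 1])
        assert res.groups.loc["unchanged", "percent"] == 100.0
        mat = res.matrix
        for v in a:
            assert mat.loc[v, v] == 100.0

    def test_four_patient_toy_hand_checked(self):
        a = [10, 10, 12, 15]
        b = [9, 10, 12, 14]
        res = reclassify(a, b, [1, 0, 0, 1], [0, 1, 1, 0])
        g = res.groups
        assert g.loc["downgraded", "percent"] == 50.0
        assert g.loc["unchanged", "percent"] == 50.0
        assert g.loc["upgraded", "n"] == 0
        assert g.loc["downgraded", "primary_outcome_pct"] == 100.0
        assert res.matrix.loc[10, 9] == 50.0
        assert res.matrix.loc[10, 10] == 50.0
        assert res.counts.loc[15, 14] == 1

    def test_rows_sum_to_100(self, small_cohort_frame):
        df = small_cohort_frame
        res = reclassify(df["gema_na_int"], df["gema_na_no_ascites_int"],
                         df["event"], df["disposition"] == "transplanted")
        sums = res.matrix.sum(axis=1)
        assert np.allclose(sums, 100.0)
        assert res.groups["n"].sum() == len(df)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            reclassify([10, 11], [10], [0, 1], [1, 0])


def test_evaluate_scores_end_to_end(small_cohort_frame):
    report = evaluate_scores(small_cohort_frame)
    assert report.n <= len(small_cohort_frame)
    assert set(report.concordance) == {"gema_na_cont", "gema_na_no_ascites_cont",
                                       "meld_na_cont", "meld3_cont"}
    for res in report.concordance.values():
        assert 0.5 < res.c < 1.0
    assert all(b > 0 for b in report.brier.values())
    assert ("gema_na_cont", "gema_na_no_ascites_cont") in report.comparisons
    assert report.reclassification is not None
    d = report.to_dict()
    assert "concordance" in d and d["n"] == report.n
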