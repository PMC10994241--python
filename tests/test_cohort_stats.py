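import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matchscore.cohort_stats import (
    SurvivalRecord,
    analyze_cohort,
    contingency_2x2,
    cox_fit,
    km_curve,
    logistic_fit,
    logrank_test,
    roc_cutoff,
    round_percent,
    screen_univariate,
    summarize_biomarkers,
)

from .oracles import fisher_exact_enum, grid_cox_loghr


def srecs(times, events=None):
    events = events or [True] * len(times)
    return [SurvivalRecord(t, e) for t, e in zip(times, events)]


class TestKaplanMeier:
    def test_no_censoring_median_is_sample_median(self):
        assert km_curve(srecs([1, 2, 3, 4, 5])).median_months == 3

    def test_hand_computed_product_limit_with_censoring(self):
        curve = km_curve(srecs([1, 2, 3], [False, True, True]))
        # at t=2: 2 at risk, 1 event -> S=0.5; at t=3: 1 at risk -> S=0
        lookup = dict(zip(curve.event_times, curve.survival_probs))
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[3.0] == pytest.approx(0.0)
        assert curve.median_months == 2

    def test_all_censored_median_undefined(self):
        assert km_curve(srecs([1, 2, 3], [False] * 3)).median_months is None

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(5)
        recs = srecs(rng.exponential(5, 40), list(rng.random(40) < 0.7))
        curve = km_curve(recs)
        assert (np.diff(curve.survival_probs) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 30)
        curve = km_curve(srecs(t))
        for tau, s in zip(curve.event_times, curve.survival_probs):
            assert s == pytest.approx((t > tau).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = srecs([1, 2, 3])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1)

    def test_six_patient_hand_tabulation(self):
        # groups A={1,3,5}, B={2,4,6}, all events, no ties.
        # Hand O-E tabulation: at t=1..6 expected A-deaths are
        # 3/6, 2/5, 2/4, 1/3, 1/2, 0/1 -> O-E = 3 - (0.5+0.4+0.5+1/3+0.5)
        # V = sum of n1*n2*(n-d)*d / (n^2*(n-1)) over event times
        ga, gb = srecs([1, 3, 5]), srecs([2, 4, 6])
        o_minus_e = 3 - (3/6 + 2/5 + 2/4 + 1/3 + 1/2)
        v = sum(
            n1 * n2 * d * (n - d) / (n**2 * (n - 1))
            for n, n1, n2, d in [(6, 3, 3, 1), (5, 2, 3, 1), (4, 2, 2, 1),
                                 (3, 1, 2, 1), (2, 1, 1, 1)]
        )
        chi2, p = logrank_test(ga, gb)
        assert chi2 == pytest.approx(o_minus_e**2 / v, rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(o_minus_e**2 / v, 1), rel=1e-6)

    def test_zero_event_group_warns_but_returns(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank_test(srecs([1, 2], [False, False]), srecs([1, 2]))
        assert np.isfinite(chi2)


class TestCox:
    def test_single_covariate_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        for n in (12, 20):
            x = np.array([0, 1] * (n // 2))
            t = rng.exponential(1 / np.exp(0.7 * x))
            recs = srecs(t)
            for ties in ("efron", "breslow"):
                eff = cox_fit(recs, pd.DataFrame({"x": x}), ties=ties)[0]
                oracle = np.exp(grid_cox_loghr(t, [True] * n, x))
                assert eff.estimate == pytest.approx(oracle, abs=5e-4)

    def test_constant_covariate_is_uninformative(self):
        recs = srecs([1, 2, 3, 4])
        eff = cox_fit(recs, pd.DataFrame({"x": [1, 1, 1, 1]}))[0]
        assert eff.estimate == 1.0 and eff.p_value == 1.0
        assert eff.flag == "no_information"

    def test_recovers_generating_hazard_ratio(self):
        rng = np.random.default_rng(42)
        n = 500
        x = np.r_[np.ones(n), np.zeros(n)]
        t = np.r_[rng.exponential(10.4 / np.log(2), n),
                  rng.exponential(2.8 / np.log(2), n)]
        eff = cox_fit(srecs(t), pd.DataFrame({"high": x}))[0]
        true_hr = 2.8 / 10.4
        assert abs(eff.estimate - true_hr) / true_hr < 0.15

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        true = np.log(0.5)
        errs = []
        for n in (100, 500, 2000):
            reps = []
            for _ in range(10):
                x = np.r_[np.ones(n // 2), np.zeros(n // 2)]
                t = rng.exponential(1 / np.exp(true * x))
                eff = cox_fit(srecs(t), pd.DataFrame({"x": x}))[0]
                reps.append(np.log(eff.estimate) - true)
            errs.append(np.abs(np.mean(reps)))
        assert errs[2] < errs[0] + 0.05  # noise floor, but no growing bias
        assert errs[2] < 0.05

    def test_cox_score_direction_agrees_with_logrank(self):
        rng = np.random.default_rng(12)
        x = np.r_[np.ones(30), np.zeros(30)]
        t = rng.exponential(1 / np.exp(-0.8 * x))
        eff = cox_fit(srecs(t), pd.DataFrame({"x": x}))[0]
        chi2, p_lr = logrank_test(srecs(t[x == 1]), srecs(t[x == 0]))
        assert (eff.estimate < 1) == (km_curve(srecs(t[x == 1])).median_months
                                      > km_curve(srecs(t[x == 0])).median_months)
        assert (eff.p_value < 0.05) == (p_lr < 0.05)


class TestContingency:
    @pytest.mark.parametrize("bh,nh,bl,nl,rh,rl", [
        (10, 14, 10, 41, 71, 24),
        (10, 18, 10, 37, 56, 27),
    ])
    def test_printed_rates_at_integer_rounding(self, bh, nh, bl, nl, rh, rl):
        res = contingency_2x2(bh, nh, bl, nl)
        assert round_percent(res.rate_high) == rh
        assert round_percent(res.rate_low) == rl

    def test_symmetric_table_is_null(self):
        res = contingency_2x2(1, 2, 1, 2)
        assert res.odds_ratio == pytest.approx(1)
        assert res.fisher_p == pytest.approx(1)

    def test_fisher_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            nh, nl = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            bh, bl = int(rng.integers(0, nh + 1)), int(rng.integers(0, nl + 1))
            res = contingency_2x2(bh, nh, bl, nl)
            expected = fisher_exact_enum(bh, nh - bh, bl, nl - bl)
            assert res.fisher_p == pytest.approx(expected, rel=1e-9)

    def test_or_invariant_under_transposition(self):
        res = contingency_2x2(10, 14, 10, 41)
        flipped = contingency_2x2(10, 41, 10, 14)
        assert res.odds_ratio == pytest.approx(1 / flipped.odds_ratio)
        assert res.fisher_p == pytest.approx(flipped.fisher_p)

    def test_zero_cell_uses_haldane_correction(self):
        res = contingency_2x2(5, 5, 0, 5)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1
        assert np.isfinite(res.or_ci[1])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2(0, 0, 1, 5)

    def test_ci_brackets_estimate(self):
        res = contingency_2x2(10, 14, 10, 41)
        assert res.or_ci[0] <= res.odds_ratio <= res.or_ci[1]


class TestLogistic:
    def test_single_binary_covariate_equals_cross_product_or(self):
        y = np.array([1] * 6 + [0] * 4 + [1] * 3 + [0] * 7)
        x = np.array([1] * 10 + [0] * 10)
        eff = logistic_fit(y, pd.DataFrame({"x": x}))[0]
        assert eff.estimate == pytest.approx((6 * 7) / (4 * 3), rel=1e-5)

    def test_complete_separation_is_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        eff = logistic_fit(y, pd.DataFrame({"x": y}))[0]
        assert eff.flag == "separation"

    def test_recovers_generating_odds_ratios(self):
        rng = np.random.default_rng(31)
        n = 2000
        x1, x2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        logit = np.log(0.5) + np.log(2.0) * x1 + np.log(0.5) * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        effs = logistic_fit(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert abs(effs[0].estimate - 2.0) / 2.0 < 0.2
        assert abs(effs[1].estimate - 0.5) / 0.5 < 0.2

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(5), pd.DataFrame({"x": np.arange(5)}))


class TestScreenAndCutoff:
    def test_screen_keeps_p_below_alpha_in_order(self):
        comps = [("MS", 0.002), ("IO", 0.063), ("matched", 0.41)]
        assert screen_univariate(comps) == ["MS", "IO"]

    def test_screen_empty_when_all_above(self):
        assert screen_univariate([("a", 0.2), ("b", 0.11)]) == []

    def test_boundary_p_exactly_alpha_excluded(self):
        assert screen_univariate([("a", 0.1)]) == []

    def test_perfectly_separating_cutoff_found(self):
        scores = [40, 50, 60, 70]
        labels = [False, False, True, True]
        assert roc_cutoff(scores, labels) == 50

    def test_tie_region_resolved_by_enumeration(self):
        # any cutoff in [20, 60) has Youden 1; ties break upward within
        # observed candidates below the first positive -> 20
        assert roc_cutoff([10, 20, 60, 80], [False, False, True, True]) == 20

    def test_uninformative_scores_give_near_zero_youden(self):
        rng = np.random.default_rng(13)
        scores = rng.random(400) * 100
        labels = rng.random(400) < 0.4
        c = roc_cutoff(scores, labels)
        pred = scores > c
        j = (pred & labels).sum() / labels.sum() \
            + (~pred & ~labels).sum() / (~labels).sum() - 1
        assert j < 0.15

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff([1, 2], [True, True])

    def test_benefit_diff_criterion(self):
        c = roc_cutoff([10, 20, 60, 80], [False, False, True, True],
                       criterion="benefit_diff")
        assert c in (20.0, 60.0) and c == 20.0


class TestAnalyzeCohort:
    def _frame(self, rng, n=300, hr=0.27, benefit=(0.71, 0.24)):
        high = rng.random(n) < 0.4
        pfs = rng.exponential(np.where(high, 10.4, 2.8) / np.log(2))
        os = pfs + rng.exponential(5 / np.log(2), n)
        ben = rng.random(n) < np.where(high, *benefit)
        return pd.DataFrame({
            "pfs_months": np.maximum(pfs, 1e-3), "pfs_event": True,
            "os_months": np.maximum(os, 1e-3), "os_event": True,
            "benefit": ben,
            "ms_high": high,
            "noise": rng.random(n) < 0.5,
        })

    def test_recovers_generating_medians_and_rates(self):
        rng = np.random.default_rng(4)
        df = self._frame(rng, n=1000)
        rep = analyze_cohort(df, ["ms_high", "noise"])
        row = rep.pfs["univariate"]["ms_high"]
        assert row["median_1"] == pytest.approx(10.4, rel=0.15)
        assert row["median_0"] == pytest.approx(2.8, rel=0.15)
        assert row["hr"] == pytest.approx(2.8 / 10.4, rel=0.2)
        ben = rep.benefit["univariate"]["ms_high"]
        assert ben["rate_1"] == pytest.approx(0.71, abs=0.05)
        assert ben["rate_0"] == pytest.approx(0.24, abs=0.05)

    def test_multivariate_skipped_with_single_selected_covariate(self):
        rng = np.random.default_rng(9)
        df = self._frame(rng, n=400)
        rep = analyze_cohort(df, ["ms_high", "noise"])
        assert rep.pfs["selected"] == ["ms_high"]
        assert rep.pfs["multivariate"] is None

    def test_sparse_covariate_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        df = self._frame(rng, n=100)
        df["rare"] = [True] + [False] * 99
        rep = analyze_cohort(df, ["ms_high", "rare"])
        assert any("rare" in w for w in rep.warnings)
        assert "rare" not in rep.pfs["univariate"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            analyze_cohort(pd.DataFrame(), ["x"])

    def test_markdown_report_renders(self):
        rng = np.random.default_rng(14)
        rep = analyze_cohort(self._frame(rng, n=200), ["ms_high"])
        md = rep.to_markdown()
        assert "ms_high" in md and "Clinical benefit" in md


class TestBiomarkerSummary:
    def test_counts_over_tested_patients(self):
        from .conftest import make_profile
        from matchscore.patient_model import ImmuneBiomarkers, MSIStatus

        profiles = []
        # 55 MSI-tested (2 high), 64 TMB-tested (15 >=10), 55 PD-L1 (17 pos)
        for i in range(70):
            bm = ImmuneBiomarkers(
                msi_status=(MSIStatus.MSI_HIGH if i < 2
                            else MSIStatus.STABLE if i < 55
                            else MSIStatus.UNKNOWN),
                tmb_mut_per_mb=(15.0 if i < 15 else 2.0) if i < 64 else None,
                pdl1_percent=(30.0 if i < 17 else 0.0) if i < 55 else None,
            )
            profiles.append(make_profile(["TP53"], patient_id=f"p{i}",
                                         biomarkers=bm))
        s = summarize_biomarkers(profiles)
        assert (s["msi_high"], s["msi_tested"]) == (2, 55)
        assert (s["tmb_ge10"], s["tmb_tested"]) == (15, 64)
        assert (s["pdl1_positive"], s["pdl1_tested"]) == (17, 55)
        assert s["msi_high_rate"] == pytest.approx(0.036, abs=0.001)
        assert s["tmb_ge10_rate"] == pytest.approx(0.23, abs=0.005)
        assert s["pdl1_positive_rate"] == pytest.approx(0.309, abs=0.001)
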