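"""Association analysis: 2x2 tables, logistic fits, stepwise, cutpoint,
Hosmer-Lemeshow, Kaplan-Meier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from hrvsurv import (
    CohortSimSpec,
    ContingencyTable2x2,
    fit_logistic,
    gam_cutpoint,
    hosmer_lemeshow,
    km_estimate,
    odds_ratio,
    simulate_cohort,
    stepwise_select,
    two_by_two,
)
from hrvsurv.exceptions import InputError
from hrvsurv.reference import table_contingency


class TestTwoByTwo:
    def test_cognitive_impairment_counts_from_published_table(self, table_cohort):
        t = two_by_two(table_cohort, "cognitive_impairment")
        assert (t.a, t.b, t.c, t.d) == (18, 11, 39, 70)

    def test_counts_partition_the_cohort(self, table_cohort):
        t = two_by_two(table_cohort, "ascites")
        assert t.n == len(table_cohort) == 138

    def test_empty_cohort_gives_all_zeros(self):
        empty = pd.DataFrame({"x": [], "event_7d": []})
        t = two_by_two(empty, "x")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_complement_predicate_swaps_columns(self, table_cohort):
        t = two_by_two(table_cohort, "jaundice")
        s = two_by_two(table_cohort, lambda df: df["jaundice"] == 0)
        assert (s.a, s.b, s.c, s.d) == (t.b, t.a, t.d, t.c)

    def test_missing_values_dropped_listwise(self, table_cohort):
        df = table_cohort.copy()
        df.loc[df.index[:5], "edema"] = np.nan
        t = two_by_two(df, "edema")
        assert t.n == 133


class TestOddsRatio:
    @pytest.mark.parametrize(
        "variable, expected",
        [
            ("male", 1.44),
            ("cognitive_impairment", 2.94),
            ("edema", 0.94),
            ("jaundice", 1.74),
            ("ascites", 2.57),
        ],
    )
    def test_published_univariate_odds_ratios(self, variable, expected):
        result = odds_ratio(table_contingency(variable))
        assert round(result.odds_ratio, 2) == expected

    def test_ecog_cross_product(self):
        # 24*45 / (5*64) = 3.375
        result = odds_ratio(table_contingency("ecog_34"))
        assert result.odds_ratio == pytest.approx(3.375, abs=1e-12)

    def test_independence_gives_unity(self):
        assert odds_ratio(ContingencyTable2x2(10, 20, 5, 10)).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_is_flagged_not_corrected(self):
        r = odds_ratio(ContingencyTable2x2(0, 5, 3, 7))
        assert not r.defined and math.isnan(r.odds_ratio)
        assert odds_ratio(ContingencyTable2x2(0, 5, 3, 7), haldane=True).defined

    @given(
        a=st.integers(1, 60), b=st.integers(1, 60),
        c=st.integers(1, 60), d=st.integers(1, 60),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_single_predictor_logistic_mle(self, a, b, c, d):
        # for a saturated 2x2 the logistic MLE equals the cross-product OR
        t = ContingencyTable2x2(a, b, c, d)
        exposed = np.concatenate([np.ones(a + c), np.zeros(b + d)])
        event = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
        df = pd.DataFrame({"exposed": exposed, "event_7d": event})
        fit = fit_logistic(df, ["exposed"])
        assert fit.odds_ratios["exposed"] == pytest.approx(
            odds_ratio(t).odds_ratio, rel=1e-6
        )


class TestFitLogistic:
    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "event_7d": [1, 1, 1, 1]})
        with pytest.raises(InputError):
            fit_logistic(df, ["x"])

    def test_separation_flagged_not_silent(self):
        n = 40
        x = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        df = pd.DataFrame({"x": x, "event_7d": x})  # perfectly separated
        fit = fit_logistic(df, ["x"])
        assert not fit.converged
        assert fit.diagnostic

    def test_ci_brackets_point_estimate(self, sim_cohort):
        fit = fit_logistic(sim_cohort, ["lnhfp_lt2", "ecog_34"])
        ors = fit.odds_ratios
        ci = fit.ci_95
        for term in ("lnhfp_lt2", "ecog_34"):
            assert ci.loc[term, "ci_low"] < ors[term] < ci.loc[term, "ci_high"]


class TestStepwiseSelect:
    def test_strong_predictor_retained_across_seeds(self):
        keep = 0
        runs = 50
        for seed in range(runs):
            g = np.random.default_rng(seed)
            n = 1000
            strong = g.integers(0, 2, n)
            nulls = {f"null{j}": g.integers(0, 2, n) for j in range(5)}
            p = expit(-1.8 + math.log(4.0) * strong)
            df = pd.DataFrame({"strong": strong, **nulls,
                               "event_7d": (g.random(n) < p).astype(int)})
            res = stepwise_select(df, ["strong", *nulls])
            keep += "strong" in res.selected
        assert keep >= 0.9 * runs

    def test_null_predictor_rarely_survives_pruning(self):
        kept = 0
        runs = 60
        for seed in range(runs):
            g = np.random.default_rng(10_000 + seed)
            n = 400
            df = pd.DataFrame({
                "null0": g.integers(0, 2, n),
                "event_7d": (g.random(n) < 0.25).astype(int),
            })
            res = stepwise_select(df, ["null0"])
            kept += "null0" in res.selected
        # entry needs p<0.15 and survival of the 0.05 prune
        assert kept / runs <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / runs)

    def test_empty_candidates_give_intercept_only(self, sim_cohort):
        res = stepwise_select(sim_cohort, [])
        assert res.selected == ()
        assert res.fit.coefficients.index.tolist() == ["intercept"]

    def test_default_entry_and_stay_thresholds(self):
        import inspect

        sig = inspect.signature(stepwise_select)
        assert sig.parameters["sle"].default == 0.15
        assert sig.parameters["sls"].default == 0.15


class TestGamCutpoint:
    def test_step_risk_locates_the_jump(self):
        g = np.random.default_rng(0)
        n = 2000
        x = g.uniform(-2, 6, n)
        p = np.where(x < 2, 0.5, 0.1)
        df = pd.DataFrame({"ln_hfp": x, "event_7d": (g.random(n) < p).astype(int)})
        cp = gam_cutpoint(df, "ln_hfp")
        assert cp.found
        assert 1.5 <= cp.raw_cutoff <= 2.5

    def test_constant_risk_flags_no_cutoff(self):
        g = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({
            "ln_hfp": g.uniform(-2, 6, n),
            "event_7d": (g.random(n) < 0.3).astype(int),
        })
        cp = gam_cutpoint(df, "ln_hfp")
        assert not cp.found

    def test_symmetric_monotone_risk_crosses_near_zero(self):
        g = np.random.default_rng(1)
        n = 2000
        x = g.uniform(-3, 3, n)
        df = pd.DataFrame({"ln_hfp": x,
                           "event_7d": (g.random(n) < expit(-1.2 * x)).astype(int)})
        cp = gam_cutpoint(df, "ln_hfp", round_to=None)
        assert cp.found
        assert abs(cp.raw_cutoff) < 0.5

    def test_too_few_distinct_values_rejected(self):
        df = pd.DataFrame({"ln_hfp": [0, 1] * 50, "event_7d": [0, 1] * 50})
        with pytest.raises(InputError):
            gam_cutpoint(df, "ln_hfp")


class TestHosmerLemeshow:
    def test_null_rejection_rate_is_calibrated(self):
        rejections = 0
        runs = 200
        for seed in range(runs):
            g = np.random.default_rng(seed)
            n = 600
            x = g.standard_normal(n)
            p = expit(-1.0 + 0.8 * x)
            y = (g.random(n) < p).astype(int)
            df = pd.DataFrame({"x": x, "event_7d": y})
            fit = fit_logistic(df, ["x"])
            hl = hosmer_lemeshow(fit.fitted.to_numpy(), y)
            rejections += hl.testable and hl.p_value < 0.05
        assert 0.02 <= rejections / runs <= 0.09

    def test_two_binary_predictors_collapse_to_risk_strata(self, sim_cohort):
        fit = fit_logistic(sim_cohort, ["lnhfp_lt2", "ecog_34"])
        hl = hosmer_lemeshow(fit.fitted.to_numpy(), sim_cohort["event_7d"].to_numpy())
        assert hl.n_groups <= 4
        assert hl.df == hl.n_groups - 2

    def test_single_stratum_untestable(self):
        hl = hosmer_lemeshow(np.full(50, 0.3), np.zeros(50))
        assert not hl.testable


class TestKaplanMeier:
    def test_all_deaths_median_is_midpoint(self):
        km = km_estimate(np.arange(1.0, 10.0), np.ones(9, bool))
        assert km.median == 5.0

    def test_all_censored_flags_undefined_median(self):
        km = km_estimate(np.arange(1.0, 10.0), np.zeros(9, bool))
        assert not km.median_defined

    def test_no_censoring_reproduces_empirical_survival(self, rng):
        t = rng.integers(1, 40, 25).astype(float)
        km = km_estimate(t, np.ones(25, bool))
        for time, prob in zip(km.times, km.survival_prob):
            assert prob == pytest.approx((t > time).mean(), abs=1e-12)

    def test_hand_worked_censored_table(self):
        # 12 subjects: d=death, c=censor.  Product-limit steps computed by hand:
        # t=1: 11/12; t=2: 10/12; t=3: 10/12*8/9; t=5: *6/7; t=6: *5/6;
        # t=8: *2/3; t=10: 0.  Median = first time S <= 0.5 -> 8.
        times = np.array([1, 2, 2, 3, 4, 5, 6, 6, 7, 8, 9, 10], dtype=float)
        dead = np.array([1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1], dtype=bool)
        km = km_estimate(times, dead)
        expected = {
            1.0: 11 / 12,
            2.0: 10 / 12,
            3.0: (10 / 12) * (8 / 9),
            5.0: (10 / 12) * (8 / 9) * (6 / 7),
            6.0: (10 / 12) * (8 / 9) * (6 / 7) * (5 / 6),
            8.0: (10 / 12) * (8 / 9) * (6 / 7) * (5 / 6) * (2 / 3),
            10.0: 0.0,
        }
        curve = dict(zip(km.times, km.survival_prob))
        for t_step, s_exp in expected.items():
            assert curve[t_step] == pytest.approx(s_exp, abs=1e-12), t_step
        assert km.median == 8.0
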