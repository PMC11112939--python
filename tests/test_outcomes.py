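import numpy as np
import pandas as pd
import pytest

import nics.clinical_outcomes as co
from nics.synthetic_data import (
    TABLE3_COHORT,
    TABLE4_COHORT,
    default_cohort_model,
    reconstruct_patient_table,
    simulate_patient_cohort,
)

from oracles import chisq_oracle, logistic_oracle


class TestRate:
    @pytest.mark.parametrize(
        "num,den,expected", [(63, 90, 70.0), (0, 8, 0.0), (5, 5, 100.0), (69, 161, 42.9)]
    )
    def test_printed_values(self, num, den, expected):
        assert co.rate(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            co.rate(1, 0)

    def test_half_up_rounding(self):
        assert co.rate(1, 16) == 6.3  # 6.25 rounds up, not to even


class TestChisq2x2:
    def test_no_association(self):
        stat, p = co.chisq_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.integers(1, 200, size=(2, 2))
            for correction in (False, True):
                stat, p = co.chisq_2x2(t, correction=correction)
                o_stat, o_p = chisq_oracle(t, correction=correction)
                assert stat == pytest.approx(o_stat, abs=1e-10)
                assert p == pytest.approx(o_p, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            co.chisq_2x2([[0, 10], [0, 10]])

    def test_clinical_pregnancy_table_variant_identification(self):
        # uncorrected Pearson on the main clinical-pregnancy table agrees
        # with the independent oracle; the printed two-sided p (~0.013)
        # matches the uncorrected variant (documented, not asserted against)
        stat, p = co.chisq_2x2([[63, 27], [87, 74]], correction=False)
        o_stat, o_p = chisq_oracle([[63, 27], [87, 74]], correction=False)
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert 0.01 < p < 0.02

    def test_small_cell_case_both_variants_available(self):
        table = [[4, 8], [0, 8]]
        stat_p, p_p = co.chisq_2x2(table, correction=False)
        stat_y, p_y = co.chisq_2x2(table, correction=True)
        fisher = co.fisher_2x2(table)
        assert stat_y < stat_p  # Yates shrinks the statistic
        for variant_p in (p_p, p_y, fisher):
            assert 0 <= variant_p <= 1


class TestLogistic:
    def test_saturated_2x2_matches_closed_form(self):
        a, b, c, d = 63, 27, 87, 74
        df = pd.DataFrame(
            {
                "group": ["NICS"] * (a + b) + ["control"] * (c + d),
                "live_birth": [1] * a + [0] * b + [1] * c + [0] * d,
            }
        )
        fit = co.fit_logistic(df, outcome="live_birth", covariates=[])
        assert fit["group_nics"].coef == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_intercept_only_recovers_prevalence(self):
        df = pd.DataFrame({"group": ["control"] * 100, "live_birth": [1] * 37 + [0] * 63})
        fit = co.fit_logistic(df, outcome="live_birth", covariates=[], include_group=False)
        from scipy.special import expit

        assert expit(fit["intercept"].coef) == pytest.approx(0.37, abs=1e-10)

    def test_matches_statsmodels_oracle(self):
        model = default_cohort_model(true_or=2.0, n_nics=400, n_control=400)
        df = simulate_patient_cohort(model, np.random.default_rng(3))
        fit = co.fit_logistic(df, outcome="live_birth")
        X, names = co.build_design(df)
        coefs, ses = logistic_oracle(X, df["live_birth"].to_numpy(dtype=float))
        for j, name in enumerate(names):
            assert fit[name].coef == pytest.approx(coefs[j], abs=1e-6)
            assert fit[name].se == pytest.approx(ses[j], rel=1e-4)

    def test_null_or_recovered_at_large_n(self):
        model = default_cohort_model(true_or=1.0, n_nics=5000, n_control=5000)
        df = simulate_patient_cohort(model, np.random.default_rng(4))
        fit = co.fit_logistic(df, outcome="live_birth")
        assert 0.8 < fit["group_nics"].odds_ratio < 1.25

    def test_true_or_recovered_at_large_n(self):
        model = default_cohort_model(true_or=2.8, n_nics=5000, n_control=5000)
        df = simulate_patient_cohort(model, np.random.default_rng(5))
        fit = co.fit_logistic(df, outcome="live_birth")
        assert abs(fit["group_nics"].odds_ratio - 2.8) < 0.3

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "group": ["NICS"] * 20 + ["control"] * 20,
                "live_birth": [1] * 20 + [0] * 20,
            }
        )
        fit = co.fit_logistic(df, outcome="live_birth", covariates=[])
        assert fit.separation

    def test_rank_deficient_design_rejected(self):
        df = reconstruct_patient_table(
            type(TABLE3_COHORT)(
                name="t2", strata=TABLE3_COHORT.strata[:2], stratifier=None
            )
        )
        # female_age constant within this slice -> collinear after dummies
        df["female_age"] = np.where(df["group"] == "NICS", 35.1, 32.5)
        with pytest.raises(ValueError, match="rank"):
            co.fit_logistic(df, outcome="live_birth", covariates=["female_age"])


class TestCovariateSimulation:
    def test_arm_means_near_baseline_table(self):
        model = default_cohort_model(n_nics=2000, n_control=2000)
        df = simulate_patient_cohort(model, np.random.default_rng(6))
        nics_age = df.loc[df["group"] == "NICS", "female_age"]
        se = 4.2 / np.sqrt(len(nics_age))
        # clipping to the 22-40 eligibility window shifts the mean slightly low
        assert abs(nics_age.mean() - 35.1) < 3 * se + 0.35

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            default_cohort_model(n_nics=0)

    def test_nesting_always_satisfied(self):
        df = simulate_patient_cohort(default_cohort_model(), np.random.default_rng(7))
        co.validate_patients(df)


class TestStratifiedOutcomes:
    def test_table3_age_stratified_rates(self):
        df = reconstruct_patient_table(TABLE3_COHORT)
        res = co.stratified_outcomes(df, "age")
        old = res[">=35"]
        assert old["biochemical"].nics_rate_pct == 82.3
        assert old["clinical"].nics_rate_pct == 67.7
        assert old["ongoing"].nics_rate_pct == 56.5
        assert old["live_birth"].nics_rate_pct == 54.8
        assert old["biochemical"].control_rate_pct == 66.1
        assert old["clinical"].control_rate_pct == 32.1
        assert old["ongoing"].control_rate_pct == 25.0
        assert old["live_birth"].control_rate_pct == 25.0

    def test_table4_miscarriage_stratified_differences(self):
        df = reconstruct_patient_table(TABLE4_COHORT)
        res = co.stratified_outcomes(df, "miscarriages")
        none = res["0"]["live_birth"]
        assert none.nics_rate_pct == 61.0
        assert none.control_rate_pct == 46.9
        assert round(none.nics_rate_pct - none.control_rate_pct, 1) == 14.1
        many = res[">=2"]["live_birth"]
        assert many.nics_rate_pct == 33.3
        assert many.control_rate_pct == 0.0

    def test_constant_stratifier_degenerates_to_group_comparison(self):
        df = reconstruct_patient_table(TABLE4_COHORT)
        df["n_prior_miscarriages"] = 0
        res = co.stratified_outcomes(df, "miscarriages")
        overall = co.compare_groups(df, adjusted=False)
        for outcome in co.OUTCOME_COLUMNS:
            assert res["0"][outcome].nics_rate_pct == overall[outcome].nics_rate_pct
            assert res["1"][outcome].nics_denominator == 0

    def test_unknown_stratifier_rejected(self):
        df = reconstruct_patient_table(TABLE4_COHORT)
        with pytest.raises(ValueError, match="stratifier"):
            co.stratified_outcomes(df, "bmi")


class TestCompareGroups:
    def test_group_swap_inverts_or(self):
        model = default_cohort_model(true_or=2.0, n_nics=500, n_control=500)
        df = simulate_patient_cohort(model, np.random.default_rng(8))
        fit = co.fit_logistic(df, outcome="live_birth")
        swapped = df.copy()
        swapped["group"] = np.where(swapped["group"] == "NICS", "control", "NICS")
        fit_sw = co.fit_logistic(swapped, outcome="live_birth")
        assert fit_sw["group_nics"].odds_ratio == pytest.approx(
            1 / fit["group_nics"].odds_ratio, rel=1e-6
        )

    def test_nesting_violation_rejected_on_ingest(self):
        df = simulate_patient_cohort(default_cohort_model(), np.random.default_rng(9))
        df.loc[df.index[0], "live_birth"] = 1
        df.loc[df.index[0], "ongoing"] = 0
        with pytest.raises(ValueError, match="nesting"):
            co.compare_groups(df)

    def test_adjusted_or_recovers_generating_value(self):
        model = default_cohort_model(true_or=2.8, n_nics=1500, n_control=1500)
        df = simulate_patient_cohort(model, np.random.default_rng(10))
        report = co.compare_groups(df)
        lb = report["live_birth"]
        assert lb.ci_low < 2.8 < lb.ci_high
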