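"""Gated group comparisons, speech regression, bootstrap optimism, ordinal fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tonguekin.cohortstats import (
    bootstrap_optimism,
    compare_groups,
    fit_speech_model,
    ordinal_sensitivity,
    t_confint,
)
from tonguekin.errors import InputError, MulticollinearityError
from tonguekin.synthkin import ALS_PRESET, simulate_cohort


def als_cohort(n=2000, seed=0):
    c = simulate_cohort([ALS_PRESET], n, seed=seed)
    return c


class TestCompareGroups:
    def test_identical_groups_give_zero_t(self):
        x = np.arange(10.0)
        res = compare_groups(x, x)
        assert res.student_t == pytest.approx(0.0)
        assert res.test_used == "student_t"

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [1.0, 2.0])

    def test_matches_scipy_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = compare_groups(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.student_t == pytest.approx(float(t_ref))
        assert res.student_p == pytest.approx(float(p_ref))

    def test_gate_switches_to_mann_whitney_for_skewed_data(self, rng):
        a = rng.lognormal(0, 1.6, 200)  # heavy right skew
        b = rng.normal(1, 1, 200)
        res = compare_groups(a, b)
        assert abs(res.skewness[0]) > 2
        assert res.gate_failed
        assert res.test_used == "mann_whitney"
        assert np.isfinite(res.student_t)  # parametric result retained

    def test_type_one_error_rate_near_nominal(self):
        """Under identical normal distributions the gated test rejects at
        about the 5% level (2000 replicates)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(0.3, 0.1, 15)
            b = rng.normal(0.3, 0.1, 15)
            if compare_groups(a, b).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_recovers_study_scale_t_statistic(self):
        """Replicated draws at the calibrated group means and derived common
        SD reproduce the study-scale pooled t of about -9.6 at n = 37/20."""
        from tonguekin.synthkin import DERIVED_NORMFREQ_SD

        rng = np.random.default_rng(5)
        ts = []
        for _ in range(200):
            a = rng.normal(0.138, DERIVED_NORMFREQ_SD, 37)
            b = rng.normal(0.395, DERIVED_NORMFREQ_SD, 20)
            ts.append(compare_groups(a, b).student_t)
        mean_t = np.mean(ts)
        mc_se = np.std(ts, ddof=1) / np.sqrt(len(ts))
        assert mean_t == pytest.approx(-9.58, abs=3 * mc_se + 1e-9)


class TestSpeechModel:
    def test_noise_free_cohort_recovers_generator_coefficients_exactly(self):
        import dataclasses

        preset = dataclasses.replace(ALS_PRESET, noise_sd_speech=0.0)
        cohort = simulate_cohort([preset], 200, seed=1)
        report = fit_speech_model(cohort, outcome="speech_score_latent")
        est = report.table
        assert est.loc["intercept", "estimate"] == pytest.approx(3.34727, abs=1e-8)
        assert est.loc["age", "estimate"] == pytest.approx(-0.0074, abs=1e-8)
        assert est.loc["normalized_frequency", "estimate"] == pytest.approx(4.68230, abs=1e-8)
        assert est.loc["spasticity", "estimate"] == pytest.approx(-0.642124, abs=1e-8)
        assert report.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_large_cohort_recovers_normfreq_coefficient(self):
        report = fit_speech_model(als_cohort(4000, seed=7), outcome="speech_score_latent")
        est = report.table.loc["normalized_frequency"]
        assert est.estimate == pytest.approx(4.68, abs=3 * est.se)

    def test_independent_predictors_have_low_vif(self):
        report = fit_speech_model(als_cohort(1500, seed=3), outcome="speech_score_latent")
        assert all(v < 2 for v in report.vif.values())

    def test_ci_reconstruction_from_printed_estimate_and_se(self):
        """95% CI from estimate 4.68230, SE 1.69174 at df = 31 reproduces the
        published interval 1.23 to 8.13."""
        lo, hi = t_confint(4.68230, 1.69174, df=31)
        assert round(lo, 2) == 1.23
        assert round(hi, 2) == 8.13

    def test_report_invariants(self):
        report = fit_speech_model(als_cohort(120, seed=11), outcome="speech_score_latent")
        t = report.table
        df = report.df_resid
        tcrit = stats.t.ppf(0.975, df)
        assert np.allclose(t.ci_low, t.estimate - tcrit * t.se, atol=1e-8)
        assert np.allclose(t.ci_high, t.estimate + tcrit * t.se, atol=1e-8)
        assert report.adj_r_squared <= report.r_squared
        assert report.r == pytest.approx(np.sqrt(report.r_squared))

    def test_rank_deficiency_names_offenders(self):
        cohort = als_cohort(100, seed=2).copy()
        cohort["shadow"] = cohort["normalized_frequency"] * 2.0
        with pytest.raises(MulticollinearityError, match="shadow|normalized_frequency"):
            fit_speech_model(
                cohort,
                outcome="speech_score_latent",
                predictors=("age", "normalized_frequency", "shadow"),
            )


class TestBootstrapOptimism:
    def test_corrected_never_exceeds_apparent(self):
        for seed in range(3):
            res = bootstrap_optimism(als_cohort(37, seed=seed), B=100, seed=seed,
                                     outcome="speech_score_latent")
            assert res.corrected_r_squared <= res.apparent_r_squared + 1e-12

    def test_large_sample_optimism_vanishes(self):
        res = bootstrap_optimism(als_cohort(5000, seed=4), B=60, seed=0,
                                 outcome="speech_score_latent")
        assert res.optimism == pytest.approx(0.0, abs=0.01)
        assert res.corrected_r_squared == pytest.approx(res.apparent_r_squared, abs=0.01)

    def test_study_size_cohort_remains_stable_after_correction(self):
        res = bootstrap_optimism(als_cohort(37, seed=6), B=500, seed=1,
                                 outcome="speech_score_latent")
        assert res.apparent_r_squared - res.corrected_r_squared <= 0.25
        assert res.n_bootstrap + res.n_skipped == 500


class TestOrdinalSensitivity:
    def test_positive_monotone_effect_recovered_with_ols_sign_agreement(self):
        cohort = als_cohort(800, seed=9)
        summary = ordinal_sensitivity(cohort)
        assert summary.coef["normalized_frequency"] > 0
        assert summary.normfreq_sign_agrees_with_ols
        assert summary.p["normalized_frequency"] < 0.05

    def test_single_level_outcome_rejected(self):
        cohort = als_cohort(50, seed=1).copy()
        cohort["speech_score"] = 3
        with pytest.raises(InputError):
            ordinal_sensitivity(cohort)

    def test_permuted_outcome_is_null(self):
        """With the outcome permuted, the ordinal normalized-frequency effect
        loses significance in most replicates (permutation null)."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(10):
            cohort = als_cohort(300, seed=int(rng.integers(2**31)))
            cohort = cohort.assign(
                speech_score=rng.permutation(cohort.speech_score.to_numpy())
            )
            summary = ordinal_sensitivity(cohort)
            pvals.append(summary.p["normalized_frequency"])
        pvals = np.array(pvals)
        assert np.isnan(pvals).sum() <= 2
        assert (pvals[~np.isnan(pvals)] > 0.05).mean() >= 0.7
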