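"""Simulate an ALS/control cohort and run the clinical statistics.

Draws 37 ALS and 20 control subjects from presets calibrated to the
published group means (0.138 vs 0.395 Hz/mm), compares the groups with the
gated t-test, fits the speech regression with bootstrap optimism
correction, and runs the ordinal sensitivity analysis. The group difference
is unmistakable (|t| > 9 at these group sizes; the winsorized presets give
a somewhat larger |t| than unbounded normal draws would), and the
normalized-frequency coefficient is recovered near its generative value of
4.68 (small-sample noise applies at n = 37).
"""

from tonguekin.cohortstats import (
    bootstrap_optimism,
    compare_groups,
    fit_speech_model,
    ordinal_sensitivity,
)
from tonguekin.synthkin import ALS_PRESET, HC_PRESET, simulate_cohort

cohort = simulate_cohort([ALS_PRESET, HC_PRESET], [37, 20], seed=1)
als = cohort[cohort.group == "ALS"]
hc = cohort[cohort.group == "control"]

test = compare_groups(als.normalized_frequency, hc.normalized_frequency)
print(f"group comparison ({test.test_used}): "
      f"t = {test.student_t:.2f}, p = {test.student_p:.2g}")
print(f"  group means: ALS {als.normalized_frequency.mean():.3f}, "
      f"control {hc.normalized_frequency.mean():.3f} Hz/mm")

ols = fit_speech_model(als, outcome="speech_score")
opt = bootstrap_optimism(als, B=1000, seed=1, outcome="speech_score")
ols.optimism = opt.optimism
ols.corrected_r_squared = opt.corrected_r_squared
print()
print(ols.text_table())

ordinal = ordinal_sensitivity(als, ols_report=ols)
print()
print(f"ordinal sensitivity: normalized-frequency coefficient "
      f"{ordinal.coef['normalized_frequency']:+.2f} "
      f"(sign agrees with OLS: {ordinal.normfreq_sign_agrees_with_ols})")
print("a positive coefficient means faster-per-mm tongue movement predicts"
      " better speech scores; the ordinal model checks this is not an"
      " artifact of treating the 0-4 item as continuous.")
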