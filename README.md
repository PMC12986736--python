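# tonguekin

Video-based kinematics of the tongue lateralization task, for quantifying
bulbar motor dysfunction in ALS.

Clinical assessment of bulbar involvement (speech and swallowing
musculature) still relies on coarse ordinal scales and the examiner's eye.
A simple alternative: film the protruded tongue wagging side to side as
fast as possible for five seconds, segment the tongue in every frame with a
neural network, track the most lateral point of the mask, and summarize the
displacement signal as

```
frequency            = N_cycles / T                  [Hz]   (T = 5 s)
max_amplitude        = max |lateral displacement|    [mm]
normalized_frequency = frequency / max_amplitude     [Hz/mm]
```

The normalized frequency — cycles per second per millimetre of excursion —
is the biomarker: it separates ALS patients from controls (≈0.14 vs
≈0.40 Hz/mm) and predicts dysarthria severity in a multiple regression
alongside clinically rated tongue spasticity.

`tonguekin` is a tested re-implementation of that pipeline with no
dependence on private recordings. It provides:

* `tonguekin.synthkin` — synthetic task clips with exact ground-truth masks
  and kinematics, synthetic segmentation training sets, and synthetic
  ALS/control cohorts calibrated to the published group means and
  regression coefficients;
* `tonguekin.tonguenet` — a U-Net++ tongue segmenter (nested dense skip
  pathways) implemented in NumPy with hand-written, finite-difference-
  verified backpropagation; BCE + soft-Dice training; participant-grouped
  cross-validation with Dice/IoU evaluation;
* `tonguekin.kinemetrics` — tongue-tip tracking, hysteresis cycle counting,
  and the kinematic features above;
* `tonguekin.cohortstats` — gated group comparisons (Student t with a
  KS/skewness gate to Mann–Whitney), the speech regression with VIFs and
  bootstrap optimism correction, and an ordinal-logistic sensitivity
  analysis;
* `tonguekin.orchestrator` / a `tonguekin` CLI — end-to-end pipeline runs
  with persisted, seed-reproducible artifacts.

## Worked example

`examples/01_clip_kinematics.py` renders a clip with known truth and scores
it:

```
rendered 150 frames of 256x192 px (0.25 mm/px)
ground truth: 10 cycles, normalized frequency 0.138 Hz/mm
measured:     10 cycles, frequency 2.00 Hz, max amplitude 14.26 mm,
              normalized frequency 0.140 Hz/mm
```

A 2 Hz wag with a 14.5 mm tip excursion yields 10 complete cycles in the
5-s window; the tracker recovers the amplitude to within a pixel (0.25 mm),
and the normalized frequency lands at the ALS-typical value of ~0.14 Hz/mm.
`examples/03_cohort_statistics.py` simulates the study-sized cohort
(37 ALS / 20 controls) and prints the group test and the regression table:

```
group comparison (student_t): t = -13.15, p = 1.3e-18
  group means: ALS 0.136, control 0.395 Hz/mm

Model fit: R = 0.713, R2 = 0.509, adjusted R2 = 0.430 (N = 37)
Bootstrap optimism = 0.1584; optimism-corrected R2 = 0.350
Predictor                 Estimate       SE       t       p  95% CI
-------------------------------------------------------------------
intercept                  2.45305  0.61915   3.962   0.000  1.19 to 3.72
age                        0.00349  0.00908   0.384   0.703  -0.02 to 0.02
normalized_frequency       5.26200  1.42986   3.680   0.001  2.35 to 8.18
spasticity                -0.50644  0.17186  -2.947   0.006  -0.86 to -0.16
fasciculations            -0.31175  0.17065  -1.827   0.077  -0.66 to 0.04
jaw_jerk                  -0.00678  0.26042  -0.026   0.979  -0.54 to 0.52
```

Normalized frequency and spasticity come out as the significant speech
predictors, with coefficients near their generative values (4.68 and
−0.64; n = 37 noise applies) and all variance-inflation factors below 2.

A quick end-to-end run from the shell:

```
tonguekin e2e --profile desk --seed 7 --out run/
tonguekin train --n 24 --seed 0 --profile desk --report metrics.json
```

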