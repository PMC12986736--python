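# Methods

`tonguekin` quantifies bulbar motor function from a smartphone-style tongue
lateralization task: a ~5-second frontal video of the protruded tongue
moving side to side as fast as possible. The pipeline segments the tongue
in every frame, tracks the tip laterally, counts complete oscillation
cycles, and reduces the signal to three features:

    frequency            = n_cycles / T                 (Hz, T = 5 s)
    max_amplitude        = max |lateral displacement|   (mm, one-sided)
    normalized_frequency = frequency / max_amplitude    (Hz/mm)

Normalized frequency is the primary biomarker: dividing by each subject's
own movement range removes anatomical scale, leaving a rate-per-millimetre
measure of how quickly the tongue can alternate. Because no public
recordings exist for this task, the package ships a synthetic-data module
that generates clips, segmentation training sets and clinical cohorts with
known ground truth; every quantitative claim the package makes is tested
against that ground truth.

## Synthetic task clips

A clip is a stylized perioral view: a skin-coloured field, a dark mouth
opening, and a reddish tongue rendered as a filled ellipse with a smooth
radial boundary perturbation (four low-order harmonics, ~4% amplitude).
The tongue centre follows `x(t) = A sin(2 pi f t + phase)` plus an optional
slow jaw-drift sinusoid modelling residual head motion. Defaults mirror the
acquisition protocol being emulated: 30 fps, 5 s duration, a 256-px working
width at 0.25 mm/px (~6.4 cm field of view for a camera ~15 cm from the
mouth). Per-frame illumination gain jitter (SD 2%) and Gaussian sensor
noise (SD 4/255) are applied after the binary mask is taken, so masks are
exact.

One geometric subtlety: the tracked "tip" is the most lateral mask pixel,
which for a translating ellipse of horizontal semi-axis `a_x` travels
`A + a_x`, not `A`. The clip parameter `amp_true` is therefore defined as
the one-sided excursion of the *tip*, and the centre oscillation uses
`A = amp_true - a_x` (with `amp_true > a_x` enforced). Analytic, unrendered
trajectories — used where rasterization adds nothing — are pure sinusoids
of amplitude `amp_true`.

A complete cycle is one left excursion plus one right excursion beyond a
hysteresis band, counted when the second excursion crosses the band; this
matches counting zero-crossing pairs of the clean signal. For a sinusoid of
frequency `f` observed for 5 s it yields `floor(5f)` cycles away from the
half-cycle boundary (`frac(5f)` near 0.5 rounds up, because the closing
half-excursion completes the pair).

## Tongue segmentation

A U-Net++ — a four-level encoder–decoder whose skips form a dense grid of
intermediate nodes, each receiving all previous same-depth nodes plus an
upsampled deeper node — produces one sigmoid logit per pixel. The network,
its backpropagation and its Adam optimizer are implemented directly in
NumPy (channels-last float32; convolutions as nine shifted BLAS matrix
products with scatter-accumulation on the small-channel side), and every
layer's gradients are verified against finite differences in the test
suite.

Training uses the combined loss `BCE + (1 - soft Dice)` with equal weights
and smoothing constant 1.0, Adam, batch 16. Preprocessing resizes images to
a fixed square (256 px full scale, values scaled to [0, 1]) and masks with
nearest-neighbour so they stay binary. The probability threshold is 0.5
(symmetric default; configurable). Deep supervision is off by default.

Evaluation is participant-grouped k-fold cross-validation: unique
participant keys are shuffled with the run seed and dealt round-robin into
folds, so every image is validated exactly once and no participant appears
on both sides of a fold (asserted on every run, not sampled). Dice and IoU
are computed per held-out image with the conventions both-empty = 1.0 and
one-empty = 0.0, and averaged across folds. Diagnostic labels are never an
input to this stage; the dataset container carries only images, masks and
participant keys, and training refuses containers that carry group fields.

### Scaled profile

The full recipe (256 px, 100 epochs, learning rate 1e-4, 5 folds, ~350
images) is the package default. For CPU-scale runs a reduced profile is
provided: 128-px inputs, quarter width, 15 epochs, 2 grouped folds on 120
images. Carrying the full recipe's learning rate into this profile would
make training impossible, not merely slower: with ~60 updates per fold and
Adam's per-coordinate step bounded by the learning rate, total parameter
displacement would be at most ~60 x 1e-4 = 0.006 — two orders of magnitude
below initialization scale, so no architecture could leave its random
initial function. The reduced profile therefore preserves the full recipe's
*total optimizer displacement*: the full schedule performs ~1800 updates at
1e-4 (displacement ~0.18), so the 60-update profile uses a step size of
0.18 / 60 = 3e-3. All other training constants (loss, batch size, epochs,
folds, optimizer) are unchanged.

### Synthetic training set

Images emulate heterogeneous indoor smartphone acquisition: per-participant
tongue/skin/mouth palettes (colour jitter SD 18/255), per-image pose
(rotation up to 25 degrees, centre jitter 22% of the frame), shape
perturbation, illumination gain 0.8–1.2, Gaussian blur up to 1.2 px and
sensor noise SD 3–10/255. The mouth opening's size relative to the tongue
varies from snug close-ups to the wide opening of task-video frames
(1.3–3.5 tongue widths), reflecting a training set drawn from both
web-style photographs and participant recordings — without the wide end,
a trained model generalizes poorly to rendered clips. Each participant
contributes ~3 images so grouped
cross-validation has real structure to respect. What this generator does
not emulate: specular highlights, lips/teeth occlusion, motion blur, real
skin texture, and the unbounded variety of backgrounds in web-sourced
photographs. Passing the segmentation targets on this data shows that the
architecture, loss, training loop and evaluation are correct and that the
task is learnable end to end — not that the network would match its
reported performance on real clinical video.

## Kinematics

The tip tracker takes the clip-wide median of the mask-centroid x position
as baseline; per frame the candidates are the leftmost and rightmost mask
pixels and the tip is the candidate farther from baseline (ties go left).
Displacement is converted to mm with a *supplied* mm-per-px calibration —
the package refuses to infer scale from anatomy. Empty-mask frames are
linearly interpolated and flagged; more than 10 consecutive missing frames
(~333 ms at 30 fps) fail the clip, mirroring the exclusion of clips whose
motion blur prevents reliable segmentation.

Cycle counting runs on a 5-frame centred moving average (~167 ms; long
enough to suppress single-frame segmentation jitter, short enough to pass
lateral-wag frequencies up to ~4.5 Hz), with hysteresis at 0.2 x max |d|.
Amplitude is read from the raw series so smoothing cannot attenuate peaks.
The scoring window is the first 5 s from movement onset (first sample
outside the hysteresis band), falling back to the first 5 s of the clip
with a warning when the recording is no longer than the task. Amplitudes
below 1 mm raise an error rather than produce an inflated ratio. Subjects
perform two trials; subject-level features are the element-wise mean of the
two (with a logged single-trial fallback).

## Synthetic cohorts

Per subject, normalized frequency is drawn from the group preset
(ALS mean 0.138, control mean 0.395 Hz/mm), amplitude independently
(ALS 14.5 +/- 2.0 mm; controls 7.0 +/- 0.5 mm — faster wags are smaller, a
speed/amplitude trade-off), age from the group demographics, and the three
clinical signs (tongue spasticity 30%, fasciculations 38%, brisk jaw jerk
19% in ALS) as independent Bernoulli draws.

Design choices that matter:

* **Within-group SD.** No group SDs are published for normalized frequency,
  so both groups default to the value implied by inverting the pooled
  two-sample t formula at the published means, t and group sizes
  (sd = (0.395 - 0.138) / (9.58 sqrt(1/37 + 1/20)) ~ 0.0966 Hz/mm). The
  inversion is unit-tested against the direct t computation.
* **Antithetic draws + winsorization.** Continuous covariates are drawn in
  antithetic pairs (sample mean equals the preset exactly at even n; SD
  unbiased) and winsorized symmetrically at physical floors (normalized
  frequency at 0.02 Hz/mm, amplitude at 6 mm), which preserves the mean. An
  unbounded N(0.138, 0.0966) would put ~8% of ALS subjects at non-physical
  non-positive values; the symmetric cut is the mean-preserving fix, at the
  cost of shrinking the realized ALS SD to ~0.07.
* **Whole cycles and a rate ceiling.** The implied task frequency
  `f = nf x amp` is snapped to whole cycles over 5 s (people complete
  cycles, not fractions), and subjects whose independent draws would imply
  alternation faster than 4.4 Hz keep their biomarker value but trade
  amplitude down (`amp = 4.4 / nf`) — the physiological resolution of an
  over-fast draw, and one that leaves the group mean unbiased.
* **Speech scores.** The ALSFRS-R speech item is generated from the linear
  model `3.34727 - 0.0074 age + 4.68230 nf - 0.642124 spast - 0.21589 fasc
  - 0.29142 jaw + eps`. The noise SD is calibrated so the model's
  population R-squared is 0.508: `var(eps) = var(lp) (1 - R2) / R2`, with
  `var(lp)` computed analytically from the generator's own covariate
  distributions (winsorized-normal variance in closed form). Three copies
  are emitted: the unclamped latent (the scale on which the generative
  coefficients are exactly recoverable), a [0, 4]-clamped continuous copy,
  and the rounded ordinal item (round half away from zero, clamp to 0..4).
  Clamping censors ~12% of ALS subjects at 4, so coefficient-recovery
  checks fit the latent copy; the ordinal analyses use the ordinal copy.

## Cohort statistics

Group comparisons use the pooled Student t-test as primary (Welch reported
alongside); a Lilliefors-corrected Kolmogorov–Smirnov test with estimated
parameters, combined with |skewness| > 2, gates a switch to the
Mann–Whitney U test, whose result is then reported with the parametric
numbers retained as diagnostics. With fewer than five observations the gate
cannot be assessed and passes. No multiple-testing correction is applied —
the comparisons are few and hypothesis-driven.

The speech model is OLS with two-sided p-values at df = n - k - 1 and
Student-t confidence intervals; VIFs come from auxiliary regressions;
residual normality (Shapiro–Wilk) and homoscedasticity (Breusch–Pagan) are
reported. Rank-deficient designs raise an error naming the most collinear
pair. Internal validation is Harrell's bootstrap: refit on each subject-level
resample, optimism_b = R2(boot fit on boot sample) - R2(boot fit on the
original sample), corrected = apparent - max(0, mean optimism); the clamp
at zero keeps the corrected value from exceeding the apparent one in the
large-n limit, where the raw mean optimism is a hair below zero by Monte
Carlo noise. Degenerate resamples (constant outcome, rank-deficient design)
are skipped and counted. The ordinal sensitivity analysis is a
proportional-odds cumulative-logit fit of the ordinal item; separation is
flagged by non-convergence or a standardized effect beyond ~20 logits per
predictor SD, in which case a ridge-penalized refit (lambda = 1 on slopes
only) supplies signs, without p-values.

## Problem sizes and determinism

The shipped evaluation sizes are chosen for a single-CPU workflow: 200
subjects per group for kinematic calibration (analytic trajectories;
rendering is exercised on smaller batches), 120 images / 2 folds for the
segmentation cross-validation, 2000 subjects for regression recovery, and
200 replicates for the t-statistic study. Every stochastic stage takes an
explicit seed; fixed seed and configuration reproduce outputs bit-for-bit
(rendering included). Model checkpoints embed their configuration.

## Known limitations

* The renderer is deliberately non-photorealistic; segmentation results on
  it bound nothing about real video.
* The tip tracker assumes the tongue is the only segmented object; it has
  no notion of head motion compensation or facial landmarks.
* The cycle counter's half-excursion-pair definition differs from a strict
  full-period count by at most one cycle when a recording ends mid-cycle.
* Amplitude is the maximum of the sampled displacement, which at 30 fps
  under-reads the continuous peak by up to ~2% at 2–3 Hz; group means
  inherit a correspondingly small upward bias in normalized frequency.
* The clinical-score generator treats swallowing and salivation as
  independent of the biomarker, which is the published null result for
  dysphagia but is an assumption, not a finding.
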