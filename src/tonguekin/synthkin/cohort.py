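"""Synthetic ALS / control cohorts with calibrated effect structure.

Per-subject normalized tongue-movement frequency (Hz/mm) is drawn from the
group preset; amplitude, age and clinical sign prevalences are drawn
independently; the ALSFRS-R speech item is generated from a linear model in
(age, normalized frequency, spasticity, fasciculations, jaw jerk) plus
Gaussian noise whose variance is calibrated so the generative model's
population R-squared matches a target.

Calibration choices
-------------------
* Group means of normalized frequency: ALS 0.138, control 0.395 Hz/mm.
* Within-group SD: neither group SD is published, so both default to the
  value obtained by inverting the pooled two-sample t formula at the reported
  group means, t statistic and group sizes (|t| = 9.58 at n = 37/20), giving
  ~0.0966 Hz/mm (see :func:`pooled_sd_from_t`).
* Normalized-frequency draws use antithetic Gaussian pairs (sample mean
  equals the preset exactly at even n; the SD is unbiased) and are winsorized
  symmetrically at a physical floor of 0.02 Hz/mm, which preserves the mean.
* Speech-noise SD: sigma_eps^2 = Var(linear predictor) * (1 - R2) / R2 with
  the variance computed analytically from the generator's own covariate
  distributions, so the population R2 of the speech model equals the target
  (0.508 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ParameterError

__all__ = [
    "CohortPreset",
    "ALS_PRESET",
    "HC_PRESET",
    "pooled_sd_from_t",
    "calibrate_speech_noise_sd",
    "simulate_cohort",
    "clip_spec_for_subject",
]

#: Hz/mm; draws below this are not physically meaningful (sub-0.1 cycles over
#: 5 s at realistic amplitudes), so draws are winsorized symmetrically here.
NORMFREQ_FLOOR = 0.02
#: mm; amplitude draws are winsorized here (tongue half-width plus margin).
AMPLITUDE_FLOOR_MM = 6.0
#: Hz; voluntary lateral alternation rate ceiling -- the implied whole-cycle
#: task frequency is capped here (independent draws of normalized frequency
#: and amplitude would otherwise occasionally imply non-physical rates).
MAX_CYCLE_FREQUENCY_HZ = 4.4


def pooled_sd_from_t(mean_a: float, mean_b: float, t_abs: float, n_a: int, n_b: int) -> float:
    """Common within-group SD implied by a pooled two-sample t statistic.

    Inverts t = (m_b - m_a) / (s * sqrt(1/n_a + 1/n_b)) for s. Used to set
    the within-group spread of normalized frequency from the published group
    means, |t| and group sizes.
    """
    if t_abs <= 0 or n_a < 2 or n_b < 2:
        raise ParameterError("need |t| > 0 and at least two subjects per group")
    return abs(mean_b - mean_a) / (abs(t_abs) * np.sqrt(1.0 / n_a + 1.0 / n_b))


#: default within-group SD of normalized frequency (Hz/mm), from the printed
#: group means 0.138/0.395, |t| = 9.58 and group sizes 37/20
DERIVED_NORMFREQ_SD = pooled_sd_from_t(0.138, 0.395, 9.58, 37, 20)


@dataclass(frozen=True)
class CohortPreset:
    """Generative parameters of one study group."""

    label: str
    normfreq_mean: float  # Hz/mm
    normfreq_sd: float
    amp_mean: float  # mm, one-sided tip excursion
    amp_sd: float
    age_mean: float
    age_sd: float
    p_spasticity: float
    p_fasciculations: float
    p_jaw_jerk: float
    p_male: float = 0.5
    # speech-model coefficients (ALSFRS-R speech item on covariates)
    coef_intercept: float = 4.0
    coef_age: float = 0.0
    coef_normfreq: float = 0.0
    coef_spasticity: float = 0.0
    coef_fasciculations: float = 0.0
    coef_jaw_jerk: float = 0.0
    #: population R2 used to calibrate the speech noise SD; None => noiseless
    speech_r2_target: float | None = None
    #: explicit noise SD override (score units); wins over the R2 rule
    noise_sd_speech: float | None = None
    swallow_mean: float = 4.0
    swallow_sd: float = 0.0
    saliva_mean: float = 4.0
    saliva_sd: float = 0.0

    def __post_init__(self):
        for p in (self.p_spasticity, self.p_fasciculations, self.p_jaw_jerk, self.p_male):
            if not 0 <= p <= 1:
                raise ParameterError("prevalences must lie in [0, 1]")
        if self.normfreq_mean <= 0:
            raise ParameterError("normfreq_mean must be positive")
        if min(self.normfreq_sd, self.amp_sd, self.age_sd) < 0:
            raise ParameterError("SDs must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


#: ALS group: normalized-frequency mean from the group bar plot; ages,
#: prevalences and speech-model coefficients from the cohort table and the
#: published regression table (intercept 3.34727, age -0.0074, normalized
#: frequency 4.68230, spasticity -0.642124, fasciculations -0.21589,
#: jaw jerk -0.29142); R2 target 0.508.
ALS_PRESET = CohortPreset(
    label="ALS",
    normfreq_mean=0.138,
    normfreq_sd=DERIVED_NORMFREQ_SD,
    amp_mean=14.5,
    amp_sd=2.0,
    age_mean=63.9,
    age_sd=12.4,
    p_spasticity=0.30,
    p_fasciculations=0.38,
    p_jaw_jerk=0.19,
    p_male=0.46,
    coef_intercept=3.34727,
    coef_age=-0.0074,
    coef_normfreq=4.68230,
    coef_spasticity=-0.642124,
    coef_fasciculations=-0.21589,
    coef_jaw_jerk=-0.29142,
    speech_r2_target=0.508,
    swallow_mean=3.4,
    swallow_sd=0.9,
    saliva_mean=3.6,
    saliva_sd=0.6,
)

#: healthy controls: unimpaired speech/swallowing, no UMN/LMN signs; faster,
#: smaller-amplitude lateral wags (speed/amplitude trade-off)
HC_PRESET = CohortPreset(
    label="control",
    normfreq_mean=0.395,
    normfreq_sd=DERIVED_NORMFREQ_SD,
    amp_mean=7.0,
    amp_sd=0.5,
    age_mean=61.1,
    age_sd=9.1,
    p_spasticity=0.0,
    p_fasciculations=0.0,
    p_jaw_jerk=0.0,
    p_male=0.50,
    coef_intercept=4.0,
)


def _winsorized_normal_var(sd: float, cut: float) -> float:
    """Variance of a normal(0, sd) winsorized symmetrically at +/- cut."""
    if sd == 0:
        return 0.0
    z = cut / sd
    inner = (stats.norm.cdf(z) - stats.norm.cdf(-z)) - 2 * z * stats.norm.pdf(z)
    return sd**2 * (inner + 2 * z**2 * stats.norm.cdf(-z))


def calibrate_speech_noise_sd(preset: CohortPreset) -> float:
    """Speech-noise SD from the population-R2 rule.

    sigma_eps^2 = Var(linear predictor) * (1 - R2) / R2, with the linear-
    predictor variance computed analytically from the preset's own covariate
    distributions (independent covariates: winsorized normal for normalized
    frequency, normal for age, Bernoulli for the clinical signs).
    """
    if preset.noise_sd_speech is not None:
        return preset.noise_sd_speech
    if preset.speech_r2_target is None:
        return 0.0
    r2 = preset.speech_r2_target
    if not 0 < r2 < 1:
        raise ParameterError("speech_r2_target must lie in (0, 1)")
    cut = preset.normfreq_mean - NORMFREQ_FLOOR
    var_lp = (
        preset.coef_age**2 * preset.age_sd**2
        + preset.coef_normfreq**2 * _winsorized_normal_var(preset.normfreq_sd, cut)
        + preset.coef_spasticity**2 * preset.p_spasticity * (1 - preset.p_spasticity)
        + preset.coef_fasciculations**2 * preset.p_fasciculations * (1 - preset.p_fasciculations)
        + preset.coef_jaw_jerk**2 * preset.p_jaw_jerk * (1 - preset.p_jaw_jerk)
    )
    return float(np.sqrt(var_lp * (1 - r2) / r2))


def _antithetic_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws in antithetic pairs: the sample mean equals ``mean``
    exactly at even n (variance-reduction; the SD stays unbiased)."""
    half = (n + 1) // 2
    z = rng.standard_normal(half)
    paired = np.empty(2 * half)
    paired[0::2] = z
    paired[1::2] = -z
    return mean + sd * paired[:n]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_cohort(
    presets,
    n_per_group,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort; one row per subject.

    ``presets`` is a sequence of :class:`CohortPreset`; ``n_per_group`` an int
    or matching sequence. The returned table carries, per subject: group,
    demographics, the drawn normalized frequency and amplitude (with the
    implied whole-cycle count and frequency of the 5-s task), clinical signs,
    and three speech-score columns: ``speech_score_latent`` (linear predictor
    plus noise, unclamped -- the scale on which the generative coefficients
    are exactly recoverable), ``speech_score_continuous`` (clamped to [0, 4])
    and ``speech_score`` (rounded half-away-from-zero, clamped ordinal 0-4).
    """
    presets = list(presets)
    if not presets:
        raise ParameterError("at least one cohort preset is required")
    if np.isscalar(n_per_group):
        n_per_group = [int(n_per_group)] * len(presets)
    if len(n_per_group) != len(presets):
        raise ParameterError("n_per_group must match the number of presets")

    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for preset, n in zip(presets, n_per_group):
        noise_sd = calibrate_speech_noise_sd(preset)
        cut = preset.normfreq_mean - NORMFREQ_FLOOR
        nf = _antithetic_normal(rng, preset.normfreq_mean, preset.normfreq_sd, n)
        nf = np.clip(nf, NORMFREQ_FLOOR, preset.normfreq_mean + cut)
        amp_cut = preset.amp_mean - AMPLITUDE_FLOOR_MM
        if amp_cut <= 0:
            raise ParameterError("amp_mean must exceed the amplitude floor")
        amp = _antithetic_normal(rng, preset.amp_mean, preset.amp_sd, n)
        amp = np.clip(amp, AMPLITUDE_FLOOR_MM, preset.amp_mean + amp_cut)
        age = np.clip(_antithetic_normal(rng, preset.age_mean, preset.age_sd, n), 18, 95)
        male = rng.random(n) < preset.p_male
        spast = rng.random(n) < preset.p_spasticity
        fasc = rng.random(n) < preset.p_fasciculations
        jaw = rng.random(n) < preset.p_jaw_jerk

        lp = (
            preset.coef_intercept
            + preset.coef_age * age
            + preset.coef_normfreq * nf
            + preset.coef_spasticity * spast
            + preset.coef_fasciculations * fasc
            + preset.coef_jaw_jerk * jaw
        )
        latent = lp + noise_sd * rng.standard_normal(n)
        continuous = np.clip(latent, 0.0, 4.0)
        ordinal = np.clip(_round_half_away(latent), 0, 4).astype(int)

        swallow = np.clip(
            _round_half_away(preset.swallow_mean + preset.swallow_sd * rng.standard_normal(n)),
            0, 4,
        ).astype(int)
        saliva = np.clip(
            _round_half_away(preset.saliva_mean + preset.saliva_sd * rng.standard_normal(n)),
            0, 4,
        ).astype(int)
        bulbar = ordinal + swallow + saliva

        # physiological ceiling on the alternation rate: subjects whose drawn
        # (normalized frequency, amplitude) pair would imply a faster wag
        # trade amplitude down instead, preserving their biomarker value
        amp = np.minimum(amp, MAX_CYCLE_FREQUENCY_HZ / nf)
        amp = np.maximum(amp, 4.5)
        # whole-cycle task frequency implied by the drawn biomarker values
        n_cycles = np.maximum(np.round(5.0 * nf * amp), 1).astype(int)
        freq = n_cycles / 5.0

        for k in range(n):
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "group": preset.label,
                    "age": age[k],
                    "sex": "M" if male[k] else "F",
                    "normalized_frequency": nf[k],
                    "max_amplitude_mm": amp[k],
                    "n_cycles": n_cycles[k],
                    "frequency_hz": freq[k],
                    "spasticity": bool(spast[k]),
                    "fasciculations": bool(fasc[k]),
                    "jaw_jerk": bool(jaw[k]),
                    "speech_score_latent": latent[k],
                    "speech_score_continuous": continuous[k],
                    "speech_score": ordinal[k],
                    "swallowing_score": swallow[k],
                    "salivation_score": saliva[k],
                    "bulbar_subscore": bulbar[k],
                    "dysarthria": bool(ordinal[k] < 4),
                    "dysphagia": bool(swallow[k] < 4),
                    "bulbar_dysfunction": bool(bulbar[k] < 11),
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def clip_spec_for_subject(row, seed: int, phase: float = 0.0, **overrides):
    """ClipSpec matching one cohort row (tip excursion = drawn amplitude,
    whole-cycle frequency over the 5-s task)."""
    from .clips import ClipSpec

    kwargs = dict(
        freq_true=float(row["frequency_hz"]),
        amp_true=float(row["max_amplitude_mm"]),
        phase=phase,
        seed=seed,
    )
    kwargs.update(overrides)
    return ClipSpec(**kwargs)
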