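"""End-to-end pipeline wiring: synthesize/ingest -> segment -> track ->
features -> statistics.

Each stage persists its artifacts (frames/masks as PNG directories, features
and cohorts as CSV, statistics as JSON, the resolved configuration and seed
as YAML) so stages are independently inspectable and every output is
reproducible from its logged config + seed. Segmentation and kinematics
never see diagnostic group labels; those enter only at the statistics stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tkio
from .errors import ParameterError, QualityError, DegenerateAmplitudeError
from .kinemetrics import TipTrajectory, average_trials, compute_features, extract_tip_series
from .synthkin import (
    ALS_PRESET,
    HC_PRESET,
    ClipSpec,
    analytic_tip_series,
    clip_spec_for_subject,
    render_clip,
    simulate_cohort,
)
from .cohortstats import (
    SPEECH_PREDICTORS,
    bootstrap_optimism,
    compare_groups,
    fit_speech_model,
    ordinal_sensitivity,
)

logger = logging.getLogger("tonguekin")

__all__ = ["RunConfig", "run_pipeline", "subject_features", "cohort_features"]

TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "n_cycles",
    "frequency_hz",
    "max_amplitude_mm",
    "normalized_frequency_hz_per_mm",
    "qc",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``profile`` selects problem scale: 'desk' renders nothing and uses
    analytic ground-truth trajectories; 'full' renders clips and runs the
    segmenter when a checkpoint is given.
    """

    outdir: str = "tonguekin_run"
    seed: int = 0
    profile: str = "desk"  # desk | full
    n_per_group: int = 5
    trials_per_subject: int = 2
    fps: float = 30.0
    mm_per_px: float = 0.25
    duration: float = 5.0
    render: bool = False
    checkpoint: str | None = None
    binarization_threshold: float = 0.5
    hysteresis_frac: float = 0.2
    amplitude_guard_mm: float = 1.0
    max_interp_run: int = 10
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.profile not in ("desk", "full"):
            raise ParameterError("profile must be 'desk' or 'full'")
        if self.n_per_group < 1 or self.trials_per_subject < 1:
            raise ParameterError("n_per_group and trials_per_subject must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**tkio.read_yaml(path))


def _trial_trajectory(row, trial: int, config: RunConfig, rng, model=None) -> TipTrajectory:
    """One trial's displacement series for a cohort subject.

    Trials differ by their (random) movement phase. In rendered mode the
    clip is rasterized and the ground-truth masks (or the segmenter, when a
    model is supplied) are tracked; otherwise the analytic tip path is used.
    """
    phase = float(rng.uniform(0, 2 * np.pi))
    spec = clip_spec_for_subject(
        row,
        seed=int(rng.integers(2**31)),
        phase=phase,
        fps=config.fps,
        mm_per_px=config.mm_per_px,
        duration=config.duration,
    )
    if config.render:
        frames, truth = render_clip(spec)
        masks = truth.masks
        if model is not None:
            from .tonguenet import segment_clip

            masks, empty = segment_clip(model, frames, threshold=config.binarization_threshold)
        return extract_tip_series(
            masks, fps=spec.fps, mm_per_px=spec.mm_per_px, max_interp_run=config.max_interp_run
        )
    return TipTrajectory.from_displacement(
        analytic_tip_series(spec), fps=spec.fps, mm_per_px=spec.mm_per_px
    )


def subject_features(trial_features: list):
    """Subject-level features: mean of two trials (single-trial fallback)."""
    if len(trial_features) >= 2:
        return average_trials(trial_features[0], trial_features[1])
    return average_trials(trial_features[0], None)


def cohort_features(cohort: pd.DataFrame, config: RunConfig, model=None):
    """Run track+features for every subject/trial of a simulated cohort.

    Returns (trial_rows, subject_rows) DataFrames. QC failures (too many
    missing frames, degenerate amplitude) exclude the trial with a logged
    reason rather than aborting the run.
    """
    rng = np.random.default_rng(config.seed)
    trial_rows = []
    subject_rows = []
    for _, row in cohort.iterrows():
        feats = []
        for trial in range(config.trials_per_subject):
            try:
                traj = _trial_trajectory(row, trial, config, rng, model=model)
                f = compute_features(
                    traj,
                    duration_T=config.duration,
                    hysteresis_frac=config.hysteresis_frac,
                    amplitude_guard_mm=config.amplitude_guard_mm,
                )
            except (QualityError, DegenerateAmplitudeError) as exc:
                logger.warning("excluding %s trial %d: %s", row.subject_id, trial, exc)
                trial_rows.append(
                    dict.fromkeys(TRIAL_COLUMNS) | {
                        "subject_id": row.subject_id, "trial": trial, "qc": f"excluded: {exc}"
                    }
                )
                continue
            feats.append(f)
            trial_rows.append(
                {
                    "subject_id": row.subject_id,
                    "trial": trial,
                    "qc": "ok",
                    **{
                        "n_cycles": f.n_cycles,
                        "frequency_hz": f.frequency,
                        "max_amplitude_mm": f.max_amplitude,
                        "normalized_frequency_hz_per_mm": f.normalized_frequency,
                    },
                }
            )
        if not feats:
            logger.warning("subject %s excluded entirely by QC", row.subject_id)
            continue
        sf = subject_features(feats)
        subject_rows.append(
            {
                "subject_id": row.subject_id,
                "group": row.group,
                "n_trials": len(feats),
                "n_cycles": sf.n_cycles,
                "frequency_hz": sf.frequency,
                "max_amplitude_mm": sf.max_amplitude,
                "normalized_frequency_hz_per_mm": sf.normalized_frequency,
            }
        )
    return pd.DataFrame(trial_rows), pd.DataFrame(subject_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Synthetic end-to-end run; returns a summary dict and persists artifacts.

    Stages: simulate cohort -> (render/track or analytic) trajectories ->
    trial and subject feature CSVs -> group comparison of the measured
    normalized frequency -> speech regression + bootstrap optimism + ordinal
    sensitivity on the ALS subset -> JSON report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tkio.write_yaml(outdir / "run_config.yaml", asdict(config))
    logger.info("run config + seed logged to %s", outdir / "run_config.yaml")

    cohort = simulate_cohort([ALS_PRESET, HC_PRESET], config.n_per_group, seed=config.seed)
    cohort.to_csv(outdir / "cohort.csv", index=False)

    model = None
    if config.checkpoint:
        from .tonguenet import load_model

        model = load_model(config.checkpoint)

    trial_df, subject_df = cohort_features(cohort, config, model=model)
    trial_df.to_csv(outdir / "features_trials.csv", index=False)
    merged = subject_df.drop(columns=["group"]).merge(
        cohort.drop(columns=["normalized_frequency", "max_amplitude_mm"]), on="subject_id"
    )
    merged.to_csv(outdir / "features_subjects.csv", index=False)

    als = merged[merged.group == "ALS"]
    hc = merged[merged.group == "control"]
    report: dict = {
        "n_subjects": int(len(merged)),
        "group_means": {
            "ALS": float(als.normalized_frequency_hz_per_mm.mean()),
            "control": float(hc.normalized_frequency_hz_per_mm.mean()),
        },
    }
    if len(als) >= 2 and len(hc) >= 2:
        test = compare_groups(
            als.normalized_frequency_hz_per_mm, hc.normalized_frequency_hz_per_mm
        )
        report["group_comparison"] = {
            "test_used": test.test_used,
            "statistic": test.statistic,
            "p": test.p,
            "student_t": test.student_t,
        }
    if len(als) >= len(SPEECH_PREDICTORS) + 3:
        als_stats = als.rename(
            columns={"normalized_frequency_hz_per_mm": "normalized_frequency"}
        )
        ols = fit_speech_model(als_stats)
        opt = bootstrap_optimism(als_stats, B=200, seed=config.seed)
        ols.optimism = opt.optimism
        ols.corrected_r_squared = opt.corrected_r_squared
        report["speech_model"] = ols.to_report()
        try:
            ordinal = ordinal_sensitivity(als_stats, ols_report=ols)
            report["ordinal_sensitivity"] = {
                "coef": ordinal.coef,
                "p": ordinal.p,
                "separation_flag": ordinal.separation_flag,
                "normfreq_sign_agrees_with_ols": ordinal.normfreq_sign_agrees_with_ols,
            }
        except Exception as exc:  # pragma: no cover - sensitivity is best-effort
            report["ordinal_sensitivity"] = {"error": str(exc)}
        (outdir / "speech_model.txt").write_text(ols.text_table() + "\n")
    tkio.write_json(outdir / "report.json", report)
    return report
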