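"""Tongue-tip kinematics from per-frame segmentation masks.

The lateral tongue-lateralization task is scored from a one-dimensional
displacement signal: the tongue tip (most lateral mask pixel relative to the
clip baseline) is tracked across frames, the number of complete left-right
oscillatory cycles is counted with a hysteresis state machine, and three
features are derived:

    frequency            = n_cycles / T          [Hz], T = 5 s task window
    max_amplitude        = max |displacement|    [mm], one-sided, from raw signal
    normalized_frequency = frequency / max_amplitude   [Hz/mm]

Normalization by amplitude removes inter-individual differences in anatomy
and movement range, so the normalized frequency is the primary biomarker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAmplitudeError, InputError, ParameterError, QualityError

__all__ = [
    "TipTrajectory",
    "KinematicFeatures",
    "extract_tip_series",
    "count_cycles",
    "compute_features",
    "average_trials",
    "smooth_displacement",
]

#: frames; longer runs of empty masks fail quality control (~333 ms at 30 fps)
DEFAULT_MAX_INTERP_RUN = 10
#: fraction of max |displacement| used for the hysteresis deadband
DEFAULT_HYSTERESIS_FRAC = 0.2
#: mm; normalized frequency is refused below this amplitude
DEFAULT_AMPLITUDE_GUARD_MM = 1.0
#: frames; centred moving average applied before cycle detection (~167 ms at 30 fps)
DEFAULT_SMOOTH_WINDOW = 5

FLAG_OBSERVED = "observed"
FLAG_INTERPOLATED = "interpolated"


@dataclass
class TipTrajectory:
    """Time series of signed lateral tongue-tip displacement.

    Displacement is in mm, relative to the clip baseline (median mask-centroid
    x position); rightward in the image is positive. ``flags`` records, per
    frame, whether the sample was observed or linearly interpolated across an
    empty-mask gap.
    """

    time: np.ndarray
    displacement: np.ndarray
    baseline_x_mm: float
    flags: np.ndarray
    mm_per_px: float
    fps: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.time.shape != self.displacement.shape:
            raise InputError("time and displacement must have the same length")
        if not np.all(np.isfinite(self.displacement)):
            raise InputError("displacement contains non-finite values")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise InputError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        if self.time.size == 0:
            return 0.0
        return float(self.time[-1] - self.time[0] + 1.0 / self.fps)

    @classmethod
    def from_displacement(cls, displacement, fps: float, mm_per_px: float = np.nan,
                          baseline_x_mm: float = 0.0) -> "TipTrajectory":
        """Wrap a ready-made displacement series (e.g. an analytic ground truth)."""
        displacement = np.asarray(displacement, dtype=float)
        n = displacement.size
        return cls(
            time=np.arange(n) / fps,
            displacement=displacement,
            baseline_x_mm=baseline_x_mm,
            flags=np.array([FLAG_OBSERVED] * n),
            mm_per_px=mm_per_px,
            fps=fps,
        )


@dataclass
class KinematicFeatures:
    """Cycle count and derived kinematic features of one trial (or trial mean)."""

    n_cycles: float
    duration_T: float
    frequency: float
    max_amplitude: float
    normalized_frequency: float
    window_start_s: float = 0.0
    notes: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "duration_T": self.duration_T,
            "frequency_hz": self.frequency,
            "max_amplitude_mm": self.max_amplitude,
            "normalized_frequency_hz_per_mm": self.normalized_frequency,
        }


def _mask_tip_x(mask: np.ndarray, baseline_px: float) -> float:
    """Most lateral mask column relative to baseline; ties go to the leftmost."""
    cols = np.flatnonzero(mask.any(axis=0))
    left, right = cols[0], cols[-1]
    # strict '>' keeps the leftmost candidate on ties
    return float(right) if abs(right - baseline_px) > abs(left - baseline_px) else float(left)


def extract_tip_series(
    masks,
    fps: float,
    mm_per_px: float,
    max_interp_run: int = DEFAULT_MAX_INTERP_RUN,
) -> TipTrajectory:
    """Track the tongue tip across a stack of binary masks.

    The baseline is the clip-wide median of the mask-centroid x position; per
    frame the tip is whichever of the leftmost/rightmost mask pixels lies
    farther from baseline. Empty-mask frames are linearly interpolated and
    flagged; runs longer than ``max_interp_run`` raise :class:`QualityError`.
    """
    if fps <= 0 or mm_per_px <= 0:
        raise ParameterError("fps and mm_per_px must be positive")
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise InputError("masks must be a (frames, height, width) stack")
    masks = masks.astype(bool)
    n = masks.shape[0]
    nonempty = masks.any(axis=(1, 2))
    if not nonempty.any():
        raise InputError("all masks are empty; nothing to track")

    col_idx = np.arange(masks.shape[2], dtype=float)
    centroids = np.full(n, np.nan)
    for i in np.flatnonzero(nonempty):
        weights = masks[i].sum(axis=0).astype(float)
        centroids[i] = float((col_idx * weights).sum() / weights.sum())
    baseline_px = float(np.median(centroids[nonempty]))

    tip_px = np.full(n, np.nan)
    for i in np.flatnonzero(nonempty):
        tip_px[i] = _mask_tip_x(masks[i], baseline_px)

    missing = ~nonempty
    if missing.any():
        run_lengths = _run_lengths(missing)
        if run_lengths.max() > max_interp_run:
            raise QualityError(
                f"{run_lengths.max()} consecutive empty-mask frames exceed the "
                f"interpolation limit of {max_interp_run}"
            )
        obs = np.flatnonzero(nonempty)
        tip_px[missing] = np.interp(np.flatnonzero(missing), obs, tip_px[obs])

    flags = np.where(nonempty, FLAG_OBSERVED, FLAG_INTERPOLATED)
    displacement = (tip_px - baseline_px) * mm_per_px
    return TipTrajectory(
        time=np.arange(n) / fps,
        displacement=displacement,
        baseline_x_mm=baseline_px * mm_per_px,
        flags=flags,
        mm_per_px=mm_per_px,
        fps=fps,
    )


def _run_lengths(flag: np.ndarray) -> np.ndarray:
    """Lengths of the True runs in a boolean vector (empty array if none)."""
    padded = np.concatenate(([False], flag, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return ends - starts if starts.size else np.array([0])


def smooth_displacement(d: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average with edge renormalization (window of 1 = no-op)."""
    d = np.asarray(d, dtype=float)
    window = min(window, d.size)  # 'same' convolution needs kernel <= signal
    if window <= 1 or d.size < 2:
        return d.copy()
    kernel = np.ones(window)
    num = np.convolve(d, kernel, mode="same")
    den = np.convolve(np.ones_like(d), kernel, mode="same")
    return num / den


def count_cycles(trajectory, window=None, hysteresis_frac: float = DEFAULT_HYSTERESIS_FRAC) -> int:
    """Count complete lateral oscillatory cycles in a displacement signal.

    The signal is mean-centred; a hysteresis deadband of +/- h with
    h = ``hysteresis_frac`` * max|d| suppresses jitter. Each exit from the
    deadband on the side opposite to the previous exit is an alternation
    event; one complete cycle is two alternations (a left excursion and a
    right excursion), so the count is ``n_events // 2``. Partial cycles are
    discarded. The count is invariant to sign flips and constant offsets.
    """
    if isinstance(trajectory, TipTrajectory):
        t, d = trajectory.time, trajectory.displacement
    else:
        d = np.asarray(trajectory, dtype=float)
        t = np.arange(d.size)
    if window is not None:
        t0, t1 = window
        eps = 1e-9
        if t.size == 0 or t0 < t[0] - eps or t1 > t[-1] + (t[1] - t[0] if t.size > 1 else 0) + eps:
            raise InputError("analysis window is not covered by the trajectory")
        sel = (t >= t0 - eps) & (t < t1 - eps)
        d = d[sel]
    if d.size == 0:
        return 0

    d = d - d.mean()
    peak = float(np.max(np.abs(d)))
    if peak <= 0:
        return 0
    h = hysteresis_frac * peak

    events = 0
    state = 0  # side of the last deadband exit: 0 none, +1 right, -1 left
    for value in d:
        if value > h and state != 1:
            events += 1
            state = 1
        elif value < -h and state != -1:
            events += 1
            state = -1
    return events // 2


def compute_features(
    trajectory: TipTrajectory,
    duration_T: float = 5.0,
    hysteresis_frac: float = DEFAULT_HYSTERESIS_FRAC,
    amplitude_guard_mm: float = DEFAULT_AMPLITUDE_GUARD_MM,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> KinematicFeatures:
    """Score one trial: cycle count, frequency, max amplitude, normalized frequency.

    The analysis window is the first ``duration_T`` seconds starting at
    movement onset (first sample outside the hysteresis band); if the clip is
    too short for that, the first ``duration_T`` seconds are used with a
    warning. Cycle detection runs on a lightly smoothed copy of the signal;
    the amplitude is read from the raw signal so peaks are not attenuated.
    """
    d_raw = trajectory.displacement
    t = trajectory.time
    notes = []
    if d_raw.size < 2:
        raise InputError("trajectory too short to analyse")

    centred = d_raw - d_raw.mean()
    peak = float(np.max(np.abs(centred)))
    h = hysteresis_frac * peak
    beyond = np.flatnonzero(np.abs(centred) > h)
    onset = t[beyond[0]] if beyond.size else t[0]
    end = t[-1] + 1.0 / trajectory.fps
    if onset + duration_T > end + 1e-9:
        if duration_T > end - t[0] + 1e-9:
            notes.append("clip shorter than the analysis window; using full clip")
        else:
            notes.append("insufficient signal after onset; using first window of clip")
            warnings.warn(notes[-1], stacklevel=2)
        onset = t[0]
    window = (float(onset), float(min(onset + duration_T, end)))

    sel = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
    smooth = smooth_displacement(d_raw, smooth_window)
    n_cycles = count_cycles(smooth[sel], hysteresis_frac=hysteresis_frac)

    max_amp = float(np.max(np.abs(d_raw[sel])))
    if max_amp < amplitude_guard_mm:
        raise DegenerateAmplitudeError(
            f"max amplitude {max_amp:.3f} mm below guard {amplitude_guard_mm} mm; "
            "normalized frequency would be unreliable"
        )
    frequency = n_cycles / duration_T
    return KinematicFeatures(
        n_cycles=float(n_cycles),
        duration_T=duration_T,
        frequency=frequency,
        max_amplitude=max_amp,
        normalized_frequency=frequency / max_amp,
        window_start_s=window[0],
        notes=tuple(notes),
    )


def average_trials(trial1: KinematicFeatures, trial2: KinematicFeatures | None = None) -> KinematicFeatures:
    """Subject-level features: element-wise mean of the two trials.

    If the second trial is missing the first is returned unchanged with a
    warning (single-trial fallback). The averaged cycle count may be
    non-integer at subject level.
    """
    if trial2 is None:
        warnings.warn("second trial missing; falling back to single-trial features", stacklevel=2)
        return trial1
    if trial1.duration_T != trial2.duration_T:
        raise ParameterError("trials were scored with different task durations")
    return KinematicFeatures(
        n_cycles=0.5 * (trial1.n_cycles + trial2.n_cycles),
        duration_T=trial1.duration_T,
        frequency=0.5 * (trial1.frequency + trial2.frequency),
        max_amplitude=0.5 * (trial1.max_amplitude + trial2.max_amplitude),
        normalized_frequency=0.5 * (trial1.normalized_frequency + trial2.normalized_frequency),
        notes=trial1.notes + trial2.notes,
    )
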