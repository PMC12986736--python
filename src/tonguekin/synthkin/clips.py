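"""Synthetic tongue-lateralization task clips with exact ground truth.

Clips emulate the acquisition protocol of the task: a frontally framed
perioral region recorded at 30 fps for at least 5 s while the protruded
tongue moves side to side as rapidly as possible. The tongue is rendered as
a filled ellipse with a smooth boundary perturbation whose centre follows

    x(t) = A * sin(2*pi*f*t + phase) + jaw drift,

over a stylized two-tone face/mouth background. ``amp_true`` is the
one-sided lateral excursion of the tongue *tip* (the most lateral mask
pixel), so the centre oscillation amplitude is ``amp_true - a_x`` where
``a_x`` is the tongue's horizontal semi-axis. Masks exactly cover the
rendered tongue pixels, and every ground-truth quantity (per-frame tip
displacement, cycle count, normalized frequency) is returned alongside the
frames, which makes the clips usable as an oracle for the segmentation and
kinematics stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import ParameterError
from ..kinemetrics import count_cycles

__all__ = ["ClipSpec", "ClipTruth", "render_clip", "analytic_tip_series"]

# stylized colours (RGB, uint8 scale)
_SKIN = np.array([205.0, 164.0, 140.0])
_MOUTH = np.array([72.0, 36.0, 40.0])
_TONGUE = np.array([188.0, 74.0, 86.0])


@dataclass(frozen=True)
class ClipSpec:
    """Parameters of one synthetic task clip.

    Defaults follow the acquisition protocol emulated here: 30 fps, 5 s task,
    256-px working width at 0.25 mm/px (~6.4 cm field of view over the
    perioral region). ``jaw_drift_*`` model residual head/jaw motion that the
    instruction to keep still does not fully remove.
    """

    fps: float = 30.0
    duration: float = 5.0
    width: int = 256
    height: int = 192
    mm_per_px: float = 0.25
    freq_true: float = 2.0
    amp_true: float = 14.5  # mm, one-sided lateral excursion of the tip
    phase: float = 0.0
    tongue_axes: tuple = (4.0, 6.0)  # mm ellipse semi-axes (x, y)
    noise_sd: float = 4.0  # pixel-intensity units (uint8 scale)
    illum_jitter: float = 0.02  # relative gain SD per frame
    jaw_drift_amp: float = 0.0  # mm
    jaw_drift_freq: float = 0.3  # Hz
    boundary_jitter: float = 0.04  # relative radial perturbation amplitude
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.duration < 5:
            raise ParameterError("task duration must be at least 5 s")
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        if self.freq_true < 0 or self.amp_true < 0:
            raise ParameterError("freq_true and amp_true must be non-negative")
        if 0 < self.amp_true <= self.tongue_axes[0]:
            raise ParameterError(
                "amp_true must exceed the tongue's horizontal semi-axis "
                "(the tip excursion includes the tongue half-width)"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def centre_amplitude_mm(self) -> float:
        return max(self.amp_true - self.tongue_axes[0], 0.0)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClipTruth:
    """Ground truth of a rendered clip: per-frame masks, analytic tip path,
    complete-cycle count over the 5-s window, and the normalized frequency."""

    masks: np.ndarray  # (frames, height, width) bool
    tip_x_true: np.ndarray  # mm, per frame, relative to the rest centre
    n_cycles_true: int
    normfreq_true: float
    spec: ClipSpec = field(repr=False, default=None)


def _centre_displacement_mm(spec: ClipSpec, t: np.ndarray) -> np.ndarray:
    d = spec.centre_amplitude_mm() * np.sin(2 * np.pi * spec.freq_true * t + spec.phase)
    if spec.jaw_drift_amp:
        d = d + spec.jaw_drift_amp * np.sin(2 * np.pi * spec.jaw_drift_freq * t)
    return d


def analytic_tip_series(spec: ClipSpec) -> np.ndarray:
    """Analytic tip displacement (mm) at the frame times, without rendering.

    The tip of a rigid tongue of horizontal semi-axis a_x sits a_x beyond the
    centre on whichever side is farther from rest, so for amp_true > 0 the
    tip path is centre(t) + a_x * sign(centre(t)). For amp_true = 0 the tip
    is constant.
    """
    t = spec.frame_times()
    if spec.amp_true == 0 and spec.jaw_drift_amp == 0:
        return np.full(t.shape, -spec.tongue_axes[0])  # leftmost tie-break
    c = _centre_displacement_mm(spec, t)
    return c + spec.tongue_axes[0] * np.sign(c)


def true_cycle_count(spec: ClipSpec, window_s: float = 5.0, oversample_hz: float = 600.0) -> int:
    """Oracle cycle count: hysteresis counter on a densely sampled analytic
    centre trajectory over the first ``window_s`` seconds."""
    t = np.arange(0.0, min(window_s, spec.duration), 1.0 / oversample_hz)
    d = _centre_displacement_mm(spec, t)
    if np.max(np.abs(d)) == 0:
        return 0
    return count_cycles(d)


def render_clip(spec: ClipSpec) -> tuple[np.ndarray, ClipTruth]:
    """Render a clip; returns (frames uint8 (T,H,W,3), ClipTruth).

    Deterministic: identical spec (including seed) gives bit-identical frames
    and masks.
    """
    rng = np.random.default_rng(spec.seed)
    n, H, W = spec.n_frames, spec.height, spec.width
    t = spec.frame_times()
    centre_mm = _centre_displacement_mm(spec, t)

    cx0 = W / 2.0
    cy0 = H * 0.58
    ax = spec.tongue_axes[0] / spec.mm_per_px
    ay = spec.tongue_axes[1] / spec.mm_per_px

    # fixed smooth boundary perturbation for the whole clip
    harmonics = np.arange(2, 6)
    coef = rng.normal(0.0, spec.boundary_jitter / 2.0, harmonics.size)
    psi = rng.uniform(0, 2 * np.pi, harmonics.size)

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    # static background: skin with a dark mouth opening behind the tongue
    mouth_ax = ax + (spec.centre_amplitude_mm() + 2.0) / spec.mm_per_px
    mouth_ay = ay * 1.25
    um = (xx - cx0) / mouth_ax
    vm = (yy - cy0) / mouth_ay
    mouth = um ** 2 + vm ** 2 <= 1.0
    background = np.empty((H, W, 3))
    background[:] = _SKIN
    background[mouth] = _MOUTH

    frames = np.empty((n, H, W, 3), dtype=np.uint8)
    masks = np.empty((n, H, W), dtype=bool)
    gains = 1.0 + rng.normal(0.0, spec.illum_jitter, n)
    noise = rng.normal(0.0, spec.noise_sd, (n, H, W, 1))

    for i in range(n):
        cx = cx0 + centre_mm[i] / spec.mm_per_px
        u = (xx - cx) / ax
        v = (yy - cy0) / ay
        rho = np.sqrt(u ** 2 + v ** 2)
        theta = np.arctan2(v, u)
        bound = 1.0 + (coef[None, None, :] * np.cos(harmonics * theta[..., None] + psi)).sum(-1)
        mask = rho <= bound
        masks[i] = mask
        img = background.copy()
        img[mask] = _TONGUE
        img = img * gains[i] + noise[i]
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    tip_true = _tip_from_masks(masks, cx0) * spec.mm_per_px
    n_cycles = true_cycle_count(spec)
    normfreq = spec.freq_true / spec.amp_true if spec.amp_true > 0 else 0.0
    return frames, ClipTruth(
        masks=masks,
        tip_x_true=tip_true,
        n_cycles_true=n_cycles,
        normfreq_true=normfreq,
        spec=spec,
    )


def _tip_from_masks(masks: np.ndarray, baseline_px: float) -> np.ndarray:
    """Tip column (relative to baseline, px) per frame, most-lateral rule."""
    out = np.empty(masks.shape[0])
    for i, mask in enumerate(masks):
        cols = np.flatnonzero(mask.any(axis=0))
        left, right = cols[0], cols[-1]
        tip = right if abs(right - baseline_px) > abs(left - baseline_px) else left
        out[i] = tip - baseline_px
    return out
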