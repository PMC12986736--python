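"""Synthetic tongue image/mask pairs for segmentation training.

Stands in for a heterogeneous, manually annotated tongue-image collection:
each image shows a stylized tongue (smoothly perturbed ellipse, reddish
palette) over a two-tone face/mouth background, with randomized shape, pose,
colour, illumination, blur and sensor noise. Images are grouped under
participant keys (several images share the appearance parameters of one
"participant") so that participant-grouped cross-validation has real work to
do: leakage between folds would otherwise be undetectable.

Masks are exact binary ground truth (computed before blur/noise are applied
to the image), so segmentation metrics measured against them are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError

__all__ = ["VariabilityConfig", "SegDataset", "generate_segmentation_dataset"]


@dataclass(frozen=True)
class VariabilityConfig:
    """Ranges of the nuisance factors randomized across images.

    Defaults emulate indoor smartphone acquisition: moderate illumination
    changes (+/-20% gain), mild defocus (Gaussian blur up to ~1.2 px) and
    visible sensor noise. Tongue and skin colours are jittered per
    participant; pose and shape per image.
    """

    size: int = 128
    images_per_participant: int = 3
    tongue_radius_px: tuple = (14.0, 30.0)  # base semi-axis range
    aspect: tuple = (1.1, 1.8)  # vertical elongation of the tongue
    boundary_jitter: float = 0.06
    rotation_deg: float = 25.0
    centre_jitter: float = 0.22  # fraction of image size
    #: mouth-opening width/height relative to the tongue; the wide end covers
    #: task-video frames, where the mouth spans the tongue's whole excursion
    mouth_width_scale: tuple = (1.3, 3.5)
    mouth_height_scale: tuple = (1.1, 1.4)
    colour_jitter: float = 18.0  # uint8 units, per participant
    illumination: tuple = (0.8, 1.2)
    blur_sigma: tuple = (0.0, 1.2)
    noise_sd: tuple = (3.0, 10.0)


@dataclass
class SegDataset:
    """Aligned arrays of images, binary masks and participant keys."""

    images: np.ndarray  # (n, size, size, 3) uint8
    masks: np.ndarray  # (n, size, size) bool
    participants: np.ndarray  # (n,) int keys; several images share a key

    def __len__(self) -> int:
        return self.images.shape[0]


_SKIN = np.array([205.0, 164.0, 140.0])
_MOUTH = np.array([72.0, 36.0, 40.0])
_TONGUE = np.array([188.0, 74.0, 86.0])


def _gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return img
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img, sigma=(sigma, sigma, 0))


def generate_segmentation_dataset(
    n: int,
    config: VariabilityConfig = VariabilityConfig(),
    seed: int = 0,
) -> SegDataset:
    """Generate ``n`` image/mask pairs; deterministic for a fixed seed."""
    if n < 0:
        raise ParameterError("n must be non-negative")
    S = config.size
    images = np.empty((n, S, S, 3), dtype=np.uint8)
    masks = np.empty((n, S, S), dtype=bool)
    participants = np.empty(n, dtype=int)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    participant = -1
    for i in range(n):
        if i % config.images_per_participant == 0:
            participant += 1
            # per-participant appearance
            tongue_col = _TONGUE + rng.normal(0, config.colour_jitter, 3)
            skin_col = _SKIN + rng.normal(0, config.colour_jitter, 3)
            mouth_col = _MOUTH + rng.normal(0, config.colour_jitter / 2, 3)
            base_r = rng.uniform(*config.tongue_radius_px)
            base_aspect = rng.uniform(*config.aspect)
        participants[i] = participant

        # per-image pose and shape
        r = base_r * rng.uniform(0.85, 1.15)
        ax_, ay_ = r, r * base_aspect
        angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
        cx = S / 2 + rng.uniform(-1, 1) * config.centre_jitter * S
        cy = S * 0.55 + rng.uniform(-1, 1) * config.centre_jitter * S * 0.6
        harmonics = np.arange(2, 6)
        coef = rng.normal(0.0, config.boundary_jitter / 2, harmonics.size)
        psi = rng.uniform(0, 2 * np.pi, harmonics.size)

        dx, dy = xx - cx, yy - cy
        xr = dx * np.cos(angle) + dy * np.sin(angle)
        yr = -dx * np.sin(angle) + dy * np.cos(angle)
        u, v = xr / ax_, yr / ay_
        rho = np.sqrt(u**2 + v**2)
        theta = np.arctan2(v, u)
        bound = 1.0 + (coef[None, None, :] * np.cos(harmonics * theta[..., None] + psi)).sum(-1)
        mask = rho <= bound
        masks[i] = mask

        # mouth opening behind the tongue; width varies from snug (web-style
        # close-ups) to the wide opening seen in task-video frames
        mu = (xx - cx) / (ax_ * rng.uniform(*config.mouth_width_scale))
        mv = (yy - cy) / (ay_ * rng.uniform(*config.mouth_height_scale))
        mouth = mu**2 + mv**2 <= 1.0

        img = np.empty((S, S, 3))
        img[:] = skin_col
        img[mouth] = mouth_col
        img[mask] = tongue_col
        img = img * rng.uniform(*config.illumination)
        img = _gaussian_blur(img, rng.uniform(*config.blur_sigma))
        img = img + rng.normal(0, rng.uniform(*config.noise_sd), (S, S, 1))
        images[i] = np.clip(img, 0, 255).astype(np.uint8)

    return SegDataset(images=images, masks=masks, participants=participants)
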