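"""Image/mask preprocessing for the segmenter."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from ..errors import InputError

__all__ = ["preprocess", "preprocess_mask"]


def preprocess(image: np.ndarray, input_size: int = 256) -> np.ndarray:
    """Resize to ``input_size`` square and scale intensities to [0, 1].

    Accepts uint8 or float images, grayscale or RGB, any resolution;
    grayscale is replicated to three channels. Output is float32
    (input_size, input_size, 3) with values in [0, 1].
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("empty image")
    if image.ndim == 2:
        image = image[..., None].repeat(3, axis=-1)
    if image.ndim != 3 or image.shape[2] not in (1, 3):
        raise InputError("expected a (H, W) or (H, W, 3) image")
    if image.shape[2] == 1:
        image = image.repeat(3, axis=-1)
    img = image.astype(np.float64)
    if image.dtype == np.uint8:
        img = img / 255.0
    elif img.max() > 1.0:
        img = img / 255.0
    if img.shape[:2] != (input_size, input_size):
        img = resize(img, (input_size, input_size), anti_aliasing=True)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def preprocess_mask(mask: np.ndarray, input_size: int = 256) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask; stays strictly binary."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise InputError("empty mask")
    mask = mask.astype(bool)
    if mask.shape != (input_size, input_size):
        mask = resize(mask, (input_size, input_size), order=0, anti_aliasing=False,
                      preserve_range=True).astype(bool)
    return mask
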