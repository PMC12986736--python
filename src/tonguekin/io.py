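"""File I/O: PNG frame/mask directories, CSV tables, YAML configs, JSON reports.

Clips are exchanged as directories of numbered PNG frames (masks as 8-bit
0/255 PNGs) so no video codec is required; a best-effort video reader is
provided for environments where imageio has a suitable plugin.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import InputError

__all__ = [
    "write_frames",
    "read_frames",
    "write_masks",
    "read_masks",
    "read_video",
    "write_json",
    "read_yaml",
    "write_yaml",
]


def write_frames(directory, frames: np.ndarray, prefix: str = "frame") -> list[Path]:
    """Write (T, H, W, 3) uint8 frames as numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def read_frames(directory, prefix: str = "frame") -> np.ndarray:
    directory = Path(directory)
    paths = sorted(directory.glob(f"{prefix}_*.png"))
    if not paths:
        raise InputError(f"no {prefix}_*.png files in {directory}")
    return np.stack([iio.imread(p) for p in paths])


def write_masks(directory, masks: np.ndarray, prefix: str = "mask") -> list[Path]:
    """Write (T, H, W) boolean masks as 8-bit 0/255 PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(np.asarray(masks).astype(bool)):
        path = directory / f"{prefix}_{i:05d}.png"
        iio.imwrite(path, (mask * np.uint8(255)))
        paths.append(path)
    return paths


def read_masks(directory, prefix: str = "mask") -> np.ndarray:
    frames = read_frames(directory, prefix=prefix)
    if frames.ndim == 4:
        frames = frames[..., 0]
    return frames > 127


def read_video(path) -> np.ndarray:
    """Read a video file into a (T, H, W, 3) array; raises a clear error
    naming the file when no codec/plugin can decode it."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"video file not found: {path}")
    try:
        return np.asarray(iio.imread(path, index=None))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise InputError(
            f"could not decode video {path} (no suitable codec/plugin): {exc}"
        ) from exc


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
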