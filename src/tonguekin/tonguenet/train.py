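"""Training, participant-grouped cross-validation, and clip segmentation.

Cross-validation is grouped at the participant level: unique participant
keys are shuffled with the run seed and dealt round-robin into folds, so
folds are mutually exclusive and exhaustive over participants and no
participant contributes images to both the training and validation side of
any fold. The leakage invariant is asserted on every run, not sampled.

Diagnostic group labels are never an input to anything in this module: the
dataset container carries only images, masks and participant keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..errors import InputError, ParameterError, StateError
from .config import SegTrainConfig
from .metrics import SegMetrics, bce_softdice_from_logits, dice_iou
from .preprocess import preprocess, preprocess_mask
from .unetpp import UNetPlusPlus, build_model

__all__ = [
    "participant_folds",
    "train_model",
    "train_crossval",
    "CrossvalResult",
    "segment_clip",
    "save_model",
    "load_model",
]


def participant_folds(participants: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per image: shuffle unique participant keys, deal round-robin."""
    participants = np.asarray(participants)
    keys = np.unique(participants)
    if keys.size < n_folds:
        raise ParameterError(
            f"{keys.size} participant keys cannot fill {n_folds} grouped folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(keys)
    key_fold = {key: i % n_folds for i, key in enumerate(shuffled)}
    return np.array([key_fold[p] for p in participants])


def _prepared_arrays(dataset, config: SegTrainConfig):
    images = np.stack([preprocess(img, config.input_size) for img in dataset.images])
    masks = np.stack([preprocess_mask(m, config.input_size) for m in dataset.masks])
    return images, masks.astype(np.float32)


def train_model(
    images: np.ndarray,
    masks: np.ndarray,
    config: SegTrainConfig,
    seed: int | None = None,
) -> tuple[UNetPlusPlus, list[float]]:
    """Train a fresh model; returns (model, per-epoch mean training loss).

    ``images`` are float32 in [0, 1] at the configured input size and
    ``masks`` binary float32 of the same spatial shape.
    """
    if images.shape[0] == 0:
        raise InputError("empty training set")
    model = build_model(config)
    opt = model.make_optimizer()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = images.shape[0]
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for k in range(0, n, config.batch_size):
            idx = order[k : k + config.batch_size]
            model.zero_grad()
            logits = model.forward(images[idx], train=True)
            loss, dlogits = bce_softdice_from_logits(
                logits, masks[idx], config.w_bce, config.w_dice, config.dice_smooth
            )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.trained = True
    return model, history


@dataclass
class CrossvalResult:
    """Per-fold metrics, their across-fold mean, and the fold assignment log."""

    fold_metrics: list[SegMetrics]
    fold_assignment: np.ndarray  # fold index per image
    dice_mean: float
    iou_mean: float
    dice_sd: float
    iou_sd: float
    histories: list[list[float]] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "dice_mean": self.dice_mean,
            "dice_sd": self.dice_sd,
            "iou_mean": self.iou_mean,
            "iou_sd": self.iou_sd,
            "folds": [
                {
                    "dice_mean": m.dice_mean,
                    "dice_sd": m.dice_sd,
                    "iou_mean": m.iou_mean,
                    "iou_sd": m.iou_sd,
                    "n_images": int(m.per_image_dice.size),
                }
                for m in self.fold_metrics
            ],
        }


def train_crossval(dataset, config: SegTrainConfig) -> CrossvalResult:
    """Participant-grouped k-fold cross-validation of the segmenter.

    Every image appears in exactly one validation fold; train/validation
    participant sets are disjoint in every fold (asserted). Metrics are
    averaged across folds.
    """
    if len(dataset) == 0:
        raise InputError("empty dataset")
    for forbidden in ("group", "groups", "labels", "diagnosis"):
        if hasattr(dataset, forbidden):
            raise InputError("segmentation training must not receive diagnostic labels")
    folds = participant_folds(dataset.participants, config.n_folds, config.seed)
    images, masks = _prepared_arrays(dataset, config)

    fold_metrics = []
    histories = []
    for f in range(config.n_folds):
        val = folds == f
        train = ~val
        train_participants = set(np.asarray(dataset.participants)[train])
        val_participants = set(np.asarray(dataset.participants)[val])
        assert not (train_participants & val_participants), "participant leakage across folds"
        model, history = train_model(images[train], masks[train], config, seed=config.seed + f)
        probs = model.predict_proba(images[val])
        pred = probs >= config.threshold
        pairs = [dice_iou(p, m) for p, m in zip(pred, masks[val].astype(bool))]
        dice, iou = np.array(pairs).T
        fold_metrics.append(SegMetrics.from_pairs(dice, iou))
        histories.append(history)

    dice_means = np.array([m.dice_mean for m in fold_metrics])
    iou_means = np.array([m.iou_mean for m in fold_metrics])
    return CrossvalResult(
        fold_metrics=fold_metrics,
        fold_assignment=folds,
        dice_mean=float(dice_means.mean()),
        iou_mean=float(iou_means.mean()),
        dice_sd=float(dice_means.std(ddof=1)) if dice_means.size > 1 else 0.0,
        iou_sd=float(iou_means.std(ddof=1)) if iou_means.size > 1 else 0.0,
        histories=histories,
    )


def segment_clip(
    model: UNetPlusPlus,
    frames: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment every frame of a clip.

    Returns (masks, empty_flags): masks are binary at the source frame
    resolution (probability maps thresholded, then nearest-neighbour mapped
    back); frames whose mask area falls below ``min_area_px`` are returned
    all-background and flagged so the kinematics stage can treat them as
    missing.
    """
    if not getattr(model, "trained", False):
        raise StateError("model has not been trained; refusing to segment")
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = frames[None]
    size = model.config.input_size
    batch = np.stack([preprocess(f, size) for f in frames])
    probs = model.predict_proba(batch)
    thr = model.config.threshold if threshold is None else threshold
    small = probs >= thr

    H, W = frames.shape[1:3]
    masks = np.empty((frames.shape[0], H, W), dtype=bool)
    from skimage.transform import resize as _resize

    for i, m in enumerate(small):
        if (H, W) == m.shape:
            masks[i] = m
        else:
            masks[i] = _resize(m, (H, W), order=0, anti_aliasing=False, preserve_range=True)
    empty = masks.sum(axis=(1, 2)) < min_area_px
    masks[empty] = False
    return masks, empty


def save_model(path, model: UNetPlusPlus) -> None:
    """Serialize weights + config to a single .npz checkpoint."""
    arrays = model.state_arrays()
    np.savez_compressed(
        path,
        __config__=np.frombuffer(
            json.dumps(model.config.as_dict()).encode(), dtype=np.uint8
        ),
        __trained__=np.array([int(model.trained)]),
        **arrays,
    )


def load_model(path) -> UNetPlusPlus:
    with np.load(path) as data:
        config = SegTrainConfig(**json.loads(bytes(data["__config__"].tobytes()).decode()))
        model = build_model(config)
        model.load_state_arrays({k: data[k] for k in data.files if not k.startswith("__")})
        model.trained = bool(data["__trained__"][0])
    return model
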