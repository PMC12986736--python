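"""Segmentation network: layers, losses, metrics, grouped CV, clip segmentation."""

import numpy as np
import pytest

from tonguekin.errors import InputError, ParameterError, StateError
from tonguekin.synthkin import SegDataset, VariabilityConfig, generate_segmentation_dataset
from tonguekin.tonguenet import (
    SegTrainConfig,
    build_model,
    dice_iou,
    load_model,
    loss_bce_softdice,
    participant_folds,
    preprocess,
    preprocess_mask,
    save_model,
    segment_clip,
    train_crossval,
    train_model,
)
from tonguekin.tonguenet.metrics import bce_softdice_from_logits
from tonguekin.tonguenet.train import _prepared_arrays

TINY = dict(input_size=32, epochs=2, width_multiplier=0.0625, n_folds=2, batch_size=4)


class TestPreprocess:
    def test_resizes_and_scales_to_unit_range(self, rng):
        frame = (rng.random((1080, 1920, 3)) * 255).astype(np.uint8)
        out = preprocess(frame, 256)
        assert out.shape == (256, 256, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_on_conforming_input(self, rng):
        img = rng.random((64, 64, 3)).astype(np.float32)
        assert np.allclose(preprocess(img, 64), img, atol=1e-6)

    def test_constant_image_stays_constant(self):
        img = np.full((300, 400), 77, dtype=np.uint8)
        out = preprocess(img, 128)
        assert np.allclose(out, out.flat[0])

    def test_empty_image_rejected(self):
        with pytest.raises(InputError):
            preprocess(np.empty((0, 0)))

    def test_mask_resize_stays_binary(self):
        mask = np.zeros((100, 100), bool)
        mask[30:70, 20:60] = True
        out = preprocess_mask(mask, 64)
        assert out.dtype == bool
        assert set(np.unique(out)) <= {False, True}


class TestDiceIoU:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice_iou(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[7, 7] = True
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_counted_example_four_pixels_overlap_two(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True  # |A| = 4
        b[0, 2:] = True
        b[1, :2] = True  # |B| = 4, overlap 2
        dice, iou = dice_iou(a, b)
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(1 / 3)

    def test_empty_mask_conventions(self):
        empty = np.zeros((4, 4), bool)
        full = ~empty
        assert dice_iou(empty, empty) == (1.0, 1.0)
        assert dice_iou(empty, full) == (0.0, 0.0)

    def test_dice_iou_identity(self, rng):
        """dice = 2*iou / (1 + iou) holds per mask pair to 1e-12."""
        for _ in range(20):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            dice, iou = dice_iou(a, b)
            assert dice == pytest.approx(2 * iou / (1 + iou), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            dice_iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestLoss:
    def test_near_perfect_prediction_near_zero_loss(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = np.where(g > 0, 0.999, 0.001)
        assert loss_bce_softdice(p, g) < 0.01

    def test_uniform_half_on_four_pixels_matches_hand_computation(self):
        """p = 0.5 everywhere, 2 of 4 pixels positive: soft-Dice term is
        1 - (2*1 + eps) / (2 + 2 + eps) with eps = 1."""
        g = np.array([[1.0, 1.0], [0.0, 0.0]])
        p = np.full((2, 2), 0.5)
        expected_dice_term = 1 - (2 * 1.0 + 1.0) / (2.0 + 2.0 + 1.0)
        loss = loss_bce_softdice(p, g, w_bce=0.0, w_dice=1.0, smooth=1.0)
        assert loss == pytest.approx(expected_dice_term)

    def test_loss_decreases_toward_correct_label(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = np.where(g > 0, 0.9, 0.1)
        worse = p.copy()
        worse[0, 0] = 0.6  # move a correct pixel toward the wrong label
        assert loss_bce_softdice(p, g) < loss_bce_softdice(worse, g)

    def test_probabilities_outside_open_interval_rejected(self):
        g = np.zeros((2, 2))
        with pytest.raises(InputError):
            loss_bce_softdice(np.array([[0.0, 0.5], [0.5, 0.5]]), g)

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.normal(0, 2, (3, 8, 8)).astype(np.float32)
        g = (rng.random((3, 8, 8)) > 0.5).astype(np.float32)
        p = 1 / (1 + np.exp(-logits))
        loss_logit, _ = bce_softdice_from_logits(logits, g, 1.0, 1.0, 1.0)
        loss_prob = loss_bce_softdice(p, g, 1.0, 1.0, 1.0)
        assert loss_logit == pytest.approx(loss_prob, rel=1e-5)

    def test_gradient_matches_numerical_derivative(self, rng):
        logits = rng.normal(0, 1, (2, 4, 4)).astype(np.float64)
        g = (rng.random((2, 4, 4)) > 0.5).astype(np.float64)
        loss, grad = bce_softdice_from_logits(logits, g, 1.0, 1.0, 1.0)
        eps = 1e-5
        for idx in [(0, 1, 2), (1, 3, 0), (0, 0, 0)]:
            lp = logits.copy()
            lp[idx] += eps
            lm = logits.copy()
            lm[idx] -= eps
            num = (
                bce_softdice_from_logits(lp, g, 1.0, 1.0, 1.0)[0]
                - bce_softdice_from_logits(lm, g, 1.0, 1.0, 1.0)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestModel:
    def test_width_multiplier_scales_parameter_count(self):
        small = build_model(SegTrainConfig(**{**TINY, "width_multiplier": 0.0625}))
        large = build_model(SegTrainConfig(**{**TINY, "width_multiplier": 0.125}))
        assert small.n_parameters() < large.n_parameters()

    def test_forward_shape_and_probability_range(self, rng):
        model = build_model(SegTrainConfig(**TINY))
        x = rng.random((2, 32, 32, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 32, 32)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_fixed_seed_gives_identical_initial_weights(self):
        cfg = SegTrainConfig(**TINY, seed=42)
        w1 = build_model(cfg).state_arrays()
        w2 = build_model(cfg).state_arrays()
        assert all(np.array_equal(w1[k], w2[k]) for k in w1)

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ParameterError):
            SegTrainConfig(input_size=100)

    @pytest.mark.parametrize("layer_kind", ["conv3", "conv1", "bn", "relu", "pool", "up"])
    def test_layer_gradients_match_numerical_derivatives(self, layer_kind, rng):
        """Each layer's backward pass agrees with central finite differences
        on a random linear functional of its output."""
        from tonguekin.tonguenet.nn import (
            BatchNorm,
            Conv1x1,
            Conv3x3,
            MaxPool2,
            ReLU,
            Upsample2,
        )

        layer = {
            "conv3": lambda: Conv3x3(5, 4, rng),
            "conv1": lambda: Conv1x1(5, 4, rng),
            "bn": lambda: BatchNorm(5),
            "relu": ReLU,
            "pool": MaxPool2,
            "up": Upsample2,
        }[layer_kind]()
        if layer_kind == "pool":
            # distinct values with gaps >> eps so no argmax flips during
            # finite differencing (max pooling is non-smooth at ties)
            x = (rng.permutation(2 * 8 * 8 * 5) * 0.01).reshape(2, 8, 8, 5).astype(np.float32)
        else:
            x = rng.normal(0, 1, (2, 8, 8, 5)).astype(np.float32)
        is_bn = layer_kind == "bn"
        fwd = (lambda a: layer.forward(a, True)) if is_bn else layer.forward
        out = fwd(x)
        proj = rng.normal(0, 1, out.shape).astype(np.float32)
        eps = 1e-3

        layer.zero_grad()
        dx = layer.backward(proj)
        v = rng.normal(0, 1, x.shape).astype(np.float32)
        lp = float((fwd(x + eps * v) * proj).sum())
        lm = float((fwd(x - eps * v) * proj).sum())
        assert (lp - lm) / (2 * eps) == pytest.approx(float((dx * v).sum()), rel=2e-3)

        for p, grad in layer.params():
            fwd(x)
            layer.zero_grad()
            layer.backward(proj)
            ana = grad.copy()
            w = rng.normal(0, 1, p.shape).astype(np.float32)
            p += eps * w
            lp = float((fwd(x) * proj).sum())
            p -= 2 * eps * w
            lm = float((fwd(x) * proj).sum())
            p += eps * w
            assert (lp - lm) / (2 * eps) == pytest.approx(float((ana * w).sum()), rel=2e-3)

    def test_backprop_direction_decreases_whole_model_loss(self, rng):
        """A small step along the negative accumulated gradient lowers the
        training loss of the full nested-skip model."""
        cfg = SegTrainConfig(input_size=16, epochs=1, width_multiplier=0.0625,
                             n_folds=2, seed=0)
        model = build_model(cfg)
        for head in model.heads.values():
            head.W[...] = rng.normal(0, 0.4, head.W.shape)
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        g = (rng.random((2, 16, 16)) > 0.5).astype(np.float32)

        def loss_of():
            logits = model.forward(x, train=True)
            return bce_softdice_from_logits(logits, g, 1.0, 1.0, 1.0)

        model.zero_grad()
        loss0, dl = loss_of()
        model.backward(dl)
        gnorm2 = sum(float((grad**2).sum()) for _, grad in model.params())
        step = 1e-2 / np.sqrt(gnorm2)
        for p, grad in model.params():
            p -= step * grad
        loss1, _ = loss_of()
        assert loss1 < loss0


class TestTrainingAndCV:
    def test_grouped_folds_partition_participants(self):
        participants = np.repeat(np.arange(7), 3)
        folds = participant_folds(participants, 3, seed=0)
        assert folds.shape == participants.shape
        for f in range(3):
            in_fold = set(participants[folds == f])
            out_fold = set(participants[folds != f])
            assert not in_fold & out_fold

    def test_fewer_participants_than_folds_rejected(self):
        with pytest.raises(ParameterError):
            participant_folds(np.array([1, 1, 2, 2]), 3, seed=0)

    def test_training_loss_decreases_over_first_epochs(self):
        """Smoke property: running training loss decreases over five epochs
        on a tiny synthetic set (fixed seed)."""
        cfg = SegTrainConfig(input_size=32, epochs=5, width_multiplier=0.0625,
                             n_folds=2, batch_size=4, learning_rate=3e-3, seed=0)
        ds = generate_segmentation_dataset(8, VariabilityConfig(size=32), seed=0)
        images, masks = _prepared_arrays(ds, cfg)
        _, history = train_model(images, masks, cfg)
        assert all(b < a for a, b in zip(history, history[1:]))

    def test_crossval_every_image_validated_once_and_no_leakage(self):
        cfg = SegTrainConfig(input_size=32, epochs=1, width_multiplier=0.0625,
                             n_folds=2, batch_size=4, seed=1)
        ds = generate_segmentation_dataset(8, VariabilityConfig(size=32), seed=2)
        result = train_crossval(ds, cfg)
        assert result.fold_assignment.shape == (8,)
        assert set(result.fold_assignment) == {0, 1}
        counts = sum(m.per_image_dice.size for m in result.fold_metrics)
        assert counts == 8

    def test_training_rejects_datasets_carrying_group_labels(self):
        ds = generate_segmentation_dataset(8, VariabilityConfig(size=32), seed=2)
        labelled = SegDataset(images=ds.images, masks=ds.masks, participants=ds.participants)
        labelled.group = np.zeros(8)  # diagnosis must never reach training
        cfg = SegTrainConfig(input_size=32, epochs=1, width_multiplier=0.0625,
                             n_folds=2, batch_size=4)
        with pytest.raises(InputError):
            train_crossval(labelled, cfg)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = SegTrainConfig(**TINY, seed=3)
        ds = generate_segmentation_dataset(4, VariabilityConfig(size=32), seed=4)
        images, masks = _prepared_arrays(ds, cfg)
        model, _ = train_model(images, masks, cfg)
        path = tmp_path / "model.npz"
        save_model(path, model)
        loaded = load_model(path)
        x = rng.random((1, 32, 32, 3)).astype(np.float32)
        assert np.allclose(loaded.predict_proba(x), model.predict_proba(x), atol=1e-6)
        assert loaded.trained


class TestSegmentClip:
    def test_trained_model_segments_rendered_clip(self):
        """A model trained on the synthetic dataset segments a rendered task
        clip at median per-frame Dice >= 0.8 against the ground-truth masks
        (reduced width so the test stays a few minutes)."""
        from tonguekin.synthkin import ClipSpec, render_clip

        cfg = SegTrainConfig(input_size=128, epochs=15, learning_rate=3e-3,
                             batch_size=16, n_folds=2, width_multiplier=0.125, seed=0)
        ds = generate_segmentation_dataset(48, VariabilityConfig(size=128), seed=0)
        images, masks = _prepared_arrays(ds, cfg)
        model, _ = train_model(images, masks, cfg)
        spec = ClipSpec(freq_true=2.0, amp_true=14.5, tongue_axes=(7.0, 10.0), seed=3)
        frames, truth = render_clip(spec)
        pred, empty = segment_clip(model, frames[::10])
        dice = [dice_iou(p, m)[0] for p, m in zip(pred, truth.masks[::10])]
        assert np.median(dice) >= 0.8
        assert not empty.any()

    def test_untrained_model_refused(self, rng):
        model = build_model(SegTrainConfig(**TINY))
        with pytest.raises(StateError):
            segment_clip(model, rng.random((2, 32, 32, 3)))

    def test_one_mask_per_frame_and_empty_flagging(self, rng):
        cfg = SegTrainConfig(**TINY, seed=5)
        ds = generate_segmentation_dataset(4, VariabilityConfig(size=32), seed=5)
        images, masks = _prepared_arrays(ds, cfg)
        model, _ = train_model(images, masks, cfg)
        frames = (rng.random((3, 48, 48, 3)) * 255).astype(np.uint8)
        out, empty = segment_clip(model, frames)
        assert out.shape == (3, 48, 48)
        assert empty.shape == (3,)
        # flagged frames are returned all-background
        assert all(not out[i].any() for i in np.flatnonzero(empty))
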