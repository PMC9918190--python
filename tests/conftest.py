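"""Shared fixtures: synthetic cohorts and trained toy models.

Training fixtures are session-scoped because CPU training, while small, is
the dominant cost of the suite; every consumer treats them as read-only.
Problem sizes (64 x 128 images, tens of samples, <=200 optimization steps)
are the package's desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from meibseg.preprocessing import split_by_patient
from meibseg.segmentation import TrainConfig, train_classifier, train_segmenter
from meibseg.shape_prior import ShapePriorConfig, train_shape_prior
from meibseg.synthetic import generate_cohort, render_sample, sample_scene_params


def split_cohort(cohort, seed):
    sa = split_by_patient(cohort, seed=seed)
    by = {name: [s for s in cohort if sa.split_of(s.patient_id) == name]
          for name in ("train", "val", "test")}
    return by["train"], by["val"], by["test"]


def pooled_dice(model, samples, target="tarsus", threshold=0.5):
    from meibseg.segmentation import segment

    tp = fp = fn = 0
    for s in samples:
        pred = segment(s.image.pixels, model).seg_prob >= threshold
        gt = s.tarsus_mask if target == "tarsus" else s.gland_mask
        tp += np.sum(pred & gt)
        fp += np.sum(pred & ~gt)
        fn += np.sum(~pred & gt)
    return 2 * tp / (2 * tp + fp + fn)


@pytest.fixture(scope="session")
def easy_cohort():
    """20 easy samples (10 patients x 2 images) at test scale."""
    return generate_cohort(10, 2, seed=101, difficulty="easy",
                           image_height=64, image_width=128)


@pytest.fixture(scope="session")
def upper_masks():
    """16 training + 8 held-out easy upper-lid tarsus masks (64 x 128)."""
    masks = [
        render_sample(sample_scene_params(1000 + i, "upper", "easy", 64, 128)).tarsus_mask
        for i in range(24)
    ]
    return [m.astype(float) for m in masks[:16]], [m.astype(float) for m in masks[16:]]


@pytest.fixture(scope="session")
def toy_prior(upper_masks):
    """VAE-GAN shape prior trained 150 steps on the 16 training masks."""
    train, _ = upper_masks
    return train_shape_prior(train, ShapePriorConfig(steps=150, seed=0))


@pytest.fixture(scope="session")
def classifier_experiment():
    """Scaled-down eyelid-side classifier experiment.

    40 easy images (20 patients x 2, alternating upper/lower, 64 x 128),
    patient-level 70/20/10 split, 5 epochs at initial lr 0.001 with
    exponential decay.
    """
    from meibseg.segmentation import classify_lid

    cohort = generate_cohort(20, 2, seed=11, difficulty="easy",
                             image_height=64, image_width=128)
    train, val, test = split_cohort(cohort, seed=11)
    cfg = TrainConfig(epochs=5, batch_size=4, seed=0, base_width=16)
    model = train_classifier(train, val, cfg)
    test_acc = float(np.mean(
        [classify_lid(s.image.pixels, model)[0] == s.lid_side for s in test]
    ))
    return {"model": model, "splits": (train, val, test), "test_accuracy": test_acc}


@pytest.fixture(scope="session")
def tarsus_experiment():
    """Scaled-down tarsus segmentation with the frozen shape-prior critic.

    48 easy upper-lid images (one per patient, 64 x 128), patient-level
    split, VAE-GAN trained on the training-set tarsus masks, U-Net trained
    under the composite loss for 20 epochs (<=200 steps), threshold 0.5.
    Captures the discriminator state before and after segmenter training to
    verify the frozen contract.
    """
    cohort = generate_cohort(96, 1, seed=21, difficulty="easy",
                             image_height=64, image_width=128)
    upper = [s for s in cohort if s.lid_side == "upper"]
    assert len(upper) == 48
    train, val, test = split_cohort(upper, seed=21)
    prior = train_shape_prior(
        [s.tarsus_mask.astype(float) for s in train],
        ShapePriorConfig(steps=150, seed=0),
    )
    disc = prior.frozen_discriminator()
    disc_before = {k: v.copy() for k, v in disc.state_dict().items()}
    cfg = TrainConfig(epochs=20, batch_size=4, seed=0)
    model = train_segmenter(train, val, "tarsus", disc, cfg)
    disc_after = disc.state_dict()
    test_dice = pooled_dice(model, test)
    return {
        "model": model,
        "prior": prior,
        "splits": (train, val, test),
        "disc_before": disc_before,
        "disc_after": disc_after,
        "test_dice": float(test_dice),
    }


@pytest.fixture(scope="session")
def ablation_experiment():
    """Paired with/without shape-prior runs on hard (occluded) images.

    Three seeded training runs per arm on the same hard upper-lid split;
    held-out Dice pooled over the validation and test patients.
    """
    cohort = generate_cohort(20, 2, seed=31, difficulty="hard",
                             image_height=64, image_width=128)
    upper = [s for s in cohort if s.lid_side == "upper"]
    train, val, test = split_cohort(upper, seed=31)
    prior = train_shape_prior(
        [s.tarsus_mask.astype(float) for s in train],
        ShapePriorConfig(steps=120, seed=0),
    )
    disc = prior.frozen_discriminator()
    held = val + test
    with_prior, without_prior = [], []
    for seed in (0, 1, 2):
        cfg = TrainConfig(epochs=10, batch_size=4, seed=seed)
        m_with = train_segmenter(train, val, "tarsus", disc, cfg)
        m_without = train_segmenter(train, val, "tarsus", None, cfg)
        with_prior.append(pooled_dice(m_with, held))
        without_prior.append(pooled_dice(m_without, held))
    return {"with": with_prior, "without": without_prior}
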