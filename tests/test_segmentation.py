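"""Composite loss terms, schedules, classifier and segmenter training."""

import numpy as np
import pytest

from meibseg.models import Discriminator, UNetSegmenter
from meibseg.nn import Tensor
from meibseg.segmentation import (
    LossWeights,
    TrainConfig,
    classify_lid,
    combined_loss,
    dice_loss,
    discriminator_shape_loss,
    lr_schedule,
    reconstruction_loss,
    segment,
    train_classifier,
    train_segmenter,
)
from meibseg.synthetic import generate_cohort

RNG = np.random.default_rng(23)


def scalar(x):
    return x.item() if isinstance(x, Tensor) else float(x)


@pytest.fixture(scope="module")
def tiny_cohort():
    """Fast-training cohort: 8 patients x 1 image at 32 x 64."""
    return generate_cohort(8, 1, seed=77, difficulty="easy",
                           image_height=32, image_width=64)


class TestLossTerms:
    def test_reconstruction_identity_and_offset(self):
        img = RNG.uniform(size=(4, 4))
        assert scalar(reconstruction_loss(img, img)) == pytest.approx(0.0, abs=1e-5)
        assert scalar(
            reconstruction_loss(np.zeros((3, 3)), np.full((3, 3), 0.5))
        ) == pytest.approx(0.5, abs=1e-6)

    def test_reconstruction_matches_double_loop(self):
        a, b = RNG.uniform(size=(4, 4)), RNG.uniform(size=(4, 4))
        manual = np.mean([abs(a[i, j] - b[i, j]) for i in range(4) for j in range(4)])
        assert scalar(reconstruction_loss(a, b)) == pytest.approx(manual, abs=1e-6)

    def test_reconstruction_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_dice_perfect_and_disjoint(self):
        m = (RNG.uniform(size=(5, 5)) > 0.5).astype(float)
        assert scalar(dice_loss(m, m)) == pytest.approx(0.0, abs=1e-5)
        a = np.zeros((4, 4))
        a[:2] = 1.0
        assert scalar(dice_loss(a, 1.0 - a)) == pytest.approx(1.0, abs=1e-5)

    def test_dice_matches_direct_formula(self):
        p = RNG.uniform(size=(4, 4))
        g = (RNG.uniform(size=(4, 4)) > 0.5).astype(float)
        expect = 1 - (2 * (p * g).sum() + 1e-6) / (p.sum() + g.sum() + 1e-6)
        assert scalar(dice_loss(p, g)) == pytest.approx(expect, abs=1e-9)

    def test_dice_loss_complements_dice_index_on_hard_masks(self):
        from meibseg.evaluation import confusion, metrics

        pred = RNG.uniform(size=(6, 6)) > 0.5
        gt = RNG.uniform(size=(6, 6)) > 0.5
        index = metrics(confusion(pred, gt)).dice
        assert 1.0 - scalar(dice_loss(pred.astype(float), gt.astype(float))) == pytest.approx(
            index, abs=1e-4
        )

    def test_shape_loss_is_negative_log_score(self):
        disc = Discriminator((32, 64), rng=np.random.default_rng(1))
        p = RNG.uniform(size=(32, 64))
        score = float(disc(p[None, None]).data[0, 0])
        assert scalar(discriminator_shape_loss(p, disc)) == pytest.approx(
            -np.log(score), abs=1e-9
        )

    def test_shape_loss_monotone_in_score(self):
        disc = Discriminator((32, 64), rng=np.random.default_rng(1))
        grids = [RNG.uniform(size=(32, 64)) for _ in range(6)]
        pairs = [
            (float(disc(g[None, None]).data[0, 0]), scalar(discriminator_shape_loss(g, disc)))
            for g in grids
        ]
        pairs.sort()
        losses = [l for _, l in pairs]
        assert all(x >= y for x, y in zip(losses, losses[1:]))

    def test_shape_loss_rejects_size_mismatch(self):
        disc = Discriminator((32, 64), rng=np.random.default_rng(1))
        with pytest.raises(ValueError):
            discriminator_shape_loss(RNG.uniform(size=(16, 16)), disc)

    def test_combined_selects_dice_alone(self):
        img = RNG.uniform(size=(8, 8))
        seg = RNG.uniform(size=(8, 8))
        gt = (RNG.uniform(size=(8, 8)) > 0.5).astype(float)
        total = combined_loss(img, (seg, img), gt, LossWeights(0.0, 1.0, 0.0))
        assert scalar(total) == pytest.approx(scalar(dice_loss(seg, gt)), abs=1e-12)

    def test_combined_all_zero_weights(self):
        img = RNG.uniform(size=(4, 4))
        assert scalar(
            combined_loss(img, (img, img), img, LossWeights(0.0, 0.0, 0.0))
        ) == 0.0

    def test_combined_decomposes_termwise(self):
        disc = Discriminator((32, 64), rng=np.random.default_rng(2))
        w = LossWeights(0.3, 1.0, 0.1)
        for _ in range(100):
            img = RNG.uniform(size=(32, 64))
            seg = RNG.uniform(size=(32, 64))
            rec = RNG.uniform(size=(32, 64))
            gt = (RNG.uniform(size=(32, 64)) > 0.5).astype(float)
            total = scalar(combined_loss(img, (seg, rec), gt, w, disc))
            parts = (
                0.3 * scalar(reconstruction_loss(img, rec))
                + 1.0 * scalar(dice_loss(seg, gt))
                + 0.1 * scalar(discriminator_shape_loss(seg, disc))
            )
            assert total == pytest.approx(parts, abs=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 1.0, 0.0)

    def test_lambda3_without_discriminator_rejected(self):
        img = RNG.uniform(size=(4, 4))
        with pytest.raises(ValueError):
            combined_loss(img, (img, img), img, LossWeights(0.1, 1.0, 0.5), None)


class TestSchedule:
    def test_initial_rate(self):
        assert lr_schedule(0, TrainConfig()) == 0.001

    def test_no_decay_limit(self):
        cfg = TrainConfig(lr_gamma=1.0)
        assert lr_schedule(25, cfg) == 0.001

    def test_decay_arithmetic(self):
        cfg = TrainConfig(lr_gamma=0.98)
        assert lr_schedule(10, cfg) == pytest.approx(0.001 * 0.98**10)

    def test_rejects_negative_epoch(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestClassifier:
    def test_probabilities_sum_to_one(self, tiny_cohort):
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0, base_width=4)
        model = train_classifier(tiny_cohort[:6], tiny_cohort[6:], cfg)
        from meibseg.segmentation import _softmax

        logits = model.net(tiny_cohort[0].image.pixels).data
        assert _softmax(logits).sum() == pytest.approx(1.0, abs=1e-6)
        side, prob = classify_lid(tiny_cohort[0].image.pixels, model)
        assert side in ("upper", "lower") and 0 < prob < 1

    def test_inference_deterministic(self, tiny_cohort):
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0, base_width=4)
        model = train_classifier(tiny_cohort[:6], tiny_cohort[6:], cfg)
        a = classify_lid(tiny_cohort[1].image.pixels, model)
        b = classify_lid(tiny_cohort[1].image.pixels, model)
        assert a == b

    def test_rejects_single_class_training_set(self, tiny_cohort):
        upper_only = [s for s in tiny_cohort if s.lid_side == "upper"]
        with pytest.raises(ValueError):
            train_classifier(upper_only, tiny_cohort, TrainConfig(epochs=1))

    def test_loss_decreases_and_seeded_runs_match(self, tiny_cohort):
        cfg = TrainConfig(epochs=3, batch_size=4, seed=2, base_width=4)
        m1 = train_classifier(tiny_cohort[:6], tiny_cohort[6:], cfg)
        m2 = train_classifier(tiny_cohort[:6], tiny_cohort[6:], cfg)
        assert m1.history == m2.history
        assert m1.history[-1]["train_loss"] < m1.history[0]["train_loss"]


class TestSegmenter:
    def test_output_shapes_match_input(self):
        net = UNetSegmenter(base_width=4, rng=np.random.default_rng(0))
        for shape in [(32, 64), (30, 50)]:  # second needs internal padding
            seg, rec = net(RNG.uniform(size=shape))
            assert seg.data.shape[2:] == shape
            assert rec.data.shape[2:] == shape
            assert 0 < seg.data.min() and seg.data.max() < 1

    def test_untrained_model_reproducible(self):
        x = RNG.uniform(size=(32, 64))
        a = UNetSegmenter(base_width=4, rng=np.random.default_rng(5))(x)[0].data
        b = UNetSegmenter(base_width=4, rng=np.random.default_rng(5))(x)[0].data
        np.testing.assert_array_equal(a, b)

    def test_training_improves_validation_dice(self, tiny_cohort):
        cfg = TrainConfig(epochs=15, batch_size=4, seed=0, base_width=4)
        model = train_segmenter(tiny_cohort[:6], tiny_cohort[6:], "tarsus", None, cfg)
        dices = [h["val_dice"] for h in model.history]
        assert max(dices) > dices[0]
        out = segment(tiny_cohort[0].image.pixels, model)
        assert out.seg_prob.shape == (32, 64)

    def test_rejects_empty_sets(self):
        with pytest.raises(ValueError):
            train_segmenter([], [], "tarsus", None, TrainConfig(epochs=1))

    def test_rejects_unknown_target(self, tiny_cohort):
        with pytest.raises(ValueError):
            train_segmenter(tiny_cohort[:4], tiny_cohort[4:], "iris", None,
                            TrainConfig(epochs=1))

    def test_frozen_discriminator_untouched_by_training(self, tiny_cohort):
        disc = Discriminator((32, 64), base_width=4, rng=np.random.default_rng(9))
        before = {k: v.copy() for k, v in disc.state_dict().items()}
        cfg = TrainConfig(epochs=2, batch_size=4, seed=1, base_width=4)
        train_segmenter(tiny_cohort[:6], tiny_cohort[6:], "tarsus", disc, cfg)
        after = disc.state_dict()
        assert before.keys() == after.keys()
        for k in before:
            assert np.array_equal(before[k], after[k]), k
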