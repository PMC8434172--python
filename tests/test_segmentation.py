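import numpy as np
import pytest

from conftest import SMALL_SPEC
from usconf.phantom import generate_dataset
from usconf.segmentation import (
    SegTrainConfig,
    dice_index,
    generalized_dice_loss,
    segment,
    train_segmenter,
)
from usconf.types import EpidermisMask, UltrasoundImage


def mask_of(rows, h=30, w=10):
    g = np.zeros((h, w), bool)
    g[rows] = True
    return EpidermisMask(g)


class TestDiceIndex:
    def test_identity_is_one(self):
        m = mask_of(slice(5, 9))
        assert dice_index(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert dice_index(mask_of(slice(0, 5)), mask_of(slice(10, 15))) == 0.0

    def test_shifted_strip_half_overlap(self):
        """10-pixel strips overlapping in 5 pixels: 2*5/(10+10) = 0.5."""
        a = np.zeros((20, 1), bool)
        a[0:10] = True
        b = np.zeros((20, 1), bool)
        b[5:15] = True
        assert dice_index(EpidermisMask(a), EpidermisMask(b)) == 0.5

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = EpidermisMask(rng.random((12, 12)) > 0.6)
            b = EpidermisMask(rng.random((12, 12)) > 0.6)
            d = dice_index(a, b)
            assert d == dice_index(b, a)
            assert 0.0 <= d <= 1.0
            if not a.is_empty and d == 1.0:
                np.testing.assert_array_equal(a.grid, b.grid)

    def test_both_empty_is_one(self):
        e = EpidermisMask(np.zeros((4, 4), bool))
        assert dice_index(e, e) == 1.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_index(mask_of(slice(1, 2), h=5), mask_of(slice(1, 2), h=6))


class TestGeneralizedDiceLoss:
    def test_perfect_prediction_is_zero(self):
        t = np.zeros((2, 4, 4))
        t[1, 1:3, 1:3] = 1.0
        t[0] = 1.0 - t[1]
        assert generalized_dice_loss(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_matches_direct_summation(self):
        """Uniform 0.5/0.5 prediction on a 4x4 toy grid, equal weights:
        loss equals 1 - 2*sum(0.5*t) / sum(0.5 + t), summed by hand."""
        t = np.zeros((2, 4, 4))
        t[1, 0, :] = 1.0
        t[0] = 1.0 - t[1]
        pred = np.full((2, 4, 4), 0.5)
        num = den = 0.0
        for c in range(2):
            for i in range(4):
                for j in range(4):
                    num += 2 * 0.5 * t[c, i, j]
                    den += 0.5 + t[c, i, j]
        expected = 1.0 - num / den
        got = generalized_dice_loss(pred, t, class_weights=np.ones(2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_class_swap_symmetry(self):
        rng = np.random.default_rng(1)
        p1 = rng.random((2, 5, 5))
        pred = np.stack([p1[0], 1 - p1[0]])
        t = np.zeros((2, 5, 5))
        t[1, 2:4] = 1.0
        t[0] = 1 - t[1]
        w = np.ones(2)
        assert generalized_dice_loss(pred, t, w) == pytest.approx(
            generalized_dice_loss(pred[::-1], t[::-1], w), abs=1e-12)

    def test_monotone_along_interpolation_toward_target(self):
        t = np.zeros((2, 4, 4))
        t[1, 1:3] = 1.0
        t[0] = 1 - t[1]
        uniform = np.full((2, 4, 4), 0.5)
        losses = [
            generalized_dice_loss(uniform + lam * (t - uniform), t, np.ones(2))
            for lam in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_bad_inputs_rejected(self):
        t = np.zeros((2, 3, 3))
        t[0] = 1.0
        with pytest.raises(ValueError):
            generalized_dice_loss(t, t[:, :2])
        with pytest.raises(ValueError):
            generalized_dice_loss(t, t, class_weights=np.array([1.0, np.inf]))
        with pytest.raises(ValueError):
            generalized_dice_loss(t, t, class_weights=np.array([1.0, -1.0]))


class TestSegmenterTraining:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained(small_cohort):
        cfg = SegTrainConfig(max_epochs=25, learning_rate=0.03,
                             base_channels=6, crop_size=64, seed=3)
        return train_segmenter(small_cohort[:16], cfg), small_cohort[16:]

    def test_training_loss_recorded_and_decreasing_overall(self, trained):
        model, _ = trained
        log = model.train_log
        assert len(log) == 25
        assert log[-1] < log[0]

    def test_segment_output_contract(self, trained):
        model, held_out = trained
        pred = segment(model, held_out[0].image)
        assert pred.shape == held_out[0].image.shape
        assert pred.grid.dtype == bool
        assert pred.grid.any()

    def test_beats_all_background_predictor(self, trained):
        model, held_out = trained
        dices, trivial = [], []
        for s in held_out:
            dices.append(dice_index(segment(model, s.image), s.mask))
            empty = EpidermisMask(np.zeros(s.mask.shape, bool))
            trivial.append(dice_index(empty, s.mask))
        assert np.mean(dices) > np.mean(trivial)
        assert np.mean(dices) > 0.5

    def test_all_zero_image_does_not_crash(self, trained):
        model, held_out = trained
        img = UltrasoundImage(np.zeros((96, 64)), 0.04, 0.04)
        try:
            pred = segment(model, img)
            assert pred.shape == img.shape
        except ValueError as exc:  # empty prediction is a documented outcome
            assert "empty" in str(exc)

    def test_determinism_same_seed_same_first_epoch(self, small_cohort):
        cfg = SegTrainConfig(max_epochs=1, base_channels=4, crop_size=64, seed=9)
        a = train_segmenter(small_cohort[:4], cfg)
        b = train_segmenter(small_cohort[:4], cfg)
        assert a.train_log[0] == b.train_log[0]

    def test_too_few_or_empty_samples_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            train_segmenter(small_cohort[:1])

    def test_single_pixel_class_warns(self):
        imgs = [UltrasoundImage(np.random.default_rng(i).random((16, 16)), 0.1, 0.1)
                for i in range(2)]

        class S:
            def __init__(self, img):
                self.image = img
                self.mask = EpidermisMask(np.ones((16, 16), bool))

        cfg = SegTrainConfig(max_epochs=1, base_channels=2, augment=False)
        with pytest.warns(UserWarning, match="single pixel class"):
            train_segmenter([S(i) for i in imgs], cfg)
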