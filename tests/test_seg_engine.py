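import numpy as np
import pytest

from pelvamp.phantom import PhantomSpec, generate_phantom
from pelvamp.seg_engine import (
    SEG_CLASSES,
    DivergenceError,
    LossConfig,
    ToySegmenter,
    boundary_loss,
    combined_loss,
    combined_loss_grad,
    dice_loss,
    ensemble_predict,
    focal_loss,
    one_hot,
    organ_training_target,
    train_toy_segmenter,
)

SPACING = (0.6, 0.6, 6.0)


def _random_pred(rng, n_classes, shape):
    z = rng.normal(size=(n_classes,) + shape)
    p = np.exp(z - z.max(axis=0, keepdims=True))
    return p / p.sum(axis=0, keepdims=True)


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        target = np.array([[[0, 1], [1, 0]]])
        assert dice_loss(one_hot(target, 2), target) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_prediction_is_one(self):
        target = np.array([[[1, 1], [1, 1]]])
        pred = one_hot(np.zeros_like(target), 2)
        assert dice_loss(pred, target) == pytest.approx(1.0, abs=1e-5)

    def test_half_probability_closed_form(self):
        # 2x2x1 grid, half the voxels foreground, uniform p=0.5:
        # soft dice = (2 * 0.5*2) / (2 + 2) = 0.5 -> loss 0.5.
        target = np.array([[[1], [1]], [[0], [0]]])
        pred = np.full((2, 2, 2, 1), 0.5)
        assert dice_loss(pred, target) == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2, 2, 2)), np.zeros((3, 3, 3), dtype=int))


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        shape = (4, 4, 2)
        target = rng.integers(0, 3, size=shape)
        pred = _random_pred(rng, 3, shape)
        p_t = np.take_along_axis(pred, target[None], axis=0)[0]
        assert focal_loss(pred, target, gamma=0.0) == pytest.approx(
            float(-np.log(p_t).mean()), abs=1e-6
        )

    def test_perfect_prediction_is_zero(self):
        target = np.array([[[0, 1]]])
        assert focal_loss(one_hot(target, 2), target) == pytest.approx(0.0, abs=1e-5)

    def test_single_voxel_half_probability(self):
        # p_t = 0.5, gamma = 2: (1-0.5)^2 * ln 2 = 0.25 ln 2.
        target = np.array([[[1]]])
        pred = np.full((2, 1, 1, 1), 0.5)
        assert focal_loss(pred, target, gamma=2.0) == pytest.approx(0.25 * np.log(2))


class TestBoundaryLoss:
    def test_all_background_prediction_is_zero(self):
        target = np.zeros((4, 4, 2), dtype=int)
        target[1:3, 1:3, :] = 1
        pred = one_hot(np.zeros_like(target), 2)
        assert boundary_loss(pred, target, SPACING) == pytest.approx(0.0)

    def test_half_space_matches_hand_computed_sum(self):
        # 4x4x1 grid at unit spacing, foreground = rows 0-1.  Signed
        # distances (voxel-center EDT): rows (-2, -1, 1, 2).  A prediction
        # with foreground probability 1 everywhere averages those values.
        target = np.zeros((4, 4, 1), dtype=int)
        target[:2] = 1
        pred = np.zeros((2, 4, 4, 1))
        pred[1] = 1.0
        expected = np.mean([-2.0, -1.0, 1.0, 2.0])
        assert boundary_loss(pred, target, (1, 1, 1)) == pytest.approx(expected)

    def test_true_mask_dominates_perturbed_predictions(self):
        rng = np.random.default_rng(1)
        target = np.zeros((8, 8, 3), dtype=int)
        target[2:6, 2:6, 1] = 1
        ideal = boundary_loss(one_hot(target, 2), target, SPACING)
        for _ in range(25):
            assert ideal < boundary_loss(_random_pred(rng, 2, target.shape), target, SPACING)

    def test_empty_target_warns_and_returns_zero(self):
        target = np.zeros((4, 4, 1), dtype=int)
        pred = np.full((2, 4, 4, 1), 0.5)
        with pytest.warns(UserWarning):
            assert boundary_loss(pred, target, SPACING) == 0.0


class TestCombinedLoss:
    def test_perfect_one_hot_is_zero(self):
        target = np.array([[[0, 1], [1, 0]]])
        assert combined_loss(one_hot(target, 2), target) == pytest.approx(0.0, abs=1e-5)

    def test_decomposes_into_components(self):
        rng = np.random.default_rng(2)
        target = rng.integers(0, 2, size=(5, 5, 2))
        pred = _random_pred(rng, 2, target.shape)
        total = combined_loss(pred, target)
        assert total == pytest.approx(
            focal_loss(pred, target, 2.0) + dice_loss(pred, target), abs=1e-9
        )

    def test_focal_weight_scales_linearly(self):
        rng = np.random.default_rng(3)
        target = rng.integers(0, 2, size=(4, 4, 2))
        pred = _random_pred(rng, 2, target.shape)
        base = combined_loss(pred, target, LossConfig())
        doubled = combined_loss(pred, target, LossConfig(focal_weight=2.0))
        assert doubled - base == pytest.approx(focal_loss(pred, target, 2.0), abs=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(focal_gamma=-1)
        with pytest.raises(ValueError):
            LossConfig(dice_weight=0)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        target = rng.integers(0, 3, size=(3, 3, 2))
        logits = rng.normal(size=(3, 3, 3, 2))
        cfg = LossConfig(use_boundary=True)
        _, grad = combined_loss_grad(logits, target, cfg, SPACING)

        def loss_at(l):
            z = l - l.max(axis=0, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=0, keepdims=True)
            return combined_loss(p, target, cfg, SPACING)

        eps = 1e-6
        rng_idx = [tuple(rng.integers(0, s) for s in logits.shape) for _ in range(20)]
        for idx in rng_idx:
            up, down = logits.copy(), logits.copy()
            up[idx] += eps
            down[idx] -= eps
            numeric = (loss_at(up) - loss_at(down)) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, abs=1e-7)


class TestEnsemble:
    class _Const:
        classes = ("bg", "fg")

        def __init__(self, p):
            self.p = p

        def predict_proba(self, v):
            out = np.empty((2,) + v.data.shape)
            out[1] = self.p
            out[0] = 1 - self.p
            return out

    def test_mean_of_two_members(self, small_phantom):
        v = small_phantom.t2_volume
        probs = ensemble_predict([self._Const(0.2), self._Const(0.8)], v)
        assert np.allclose(probs[1], 0.5)
        assert np.allclose(probs.sum(axis=0), 1.0)

    def test_identical_members_equal_single(self, small_phantom):
        v = small_phantom.t2_volume
        single = self._Const(0.3).predict_proba(v)
        five = ensemble_predict([self._Const(0.3)] * 5, v)
        assert np.allclose(five, single)

    def test_matches_brute_force_average(self, small_phantom):
        rng = np.random.default_rng(5)
        ps = rng.uniform(0.1, 0.9, size=4)
        members = [self._Const(p) for p in ps]
        out = ensemble_predict(members, small_phantom.t2_volume)
        brute = np.mean([m.predict_proba(small_phantom.t2_volume) for m in members], axis=0)
        assert np.allclose(out, brute)

    def test_inconsistent_class_sets_rejected(self, small_phantom):
        bad = self._Const(0.5)
        bad.classes = ("bg", "other")
        with pytest.raises(ValueError):
            ensemble_predict([self._Const(0.5), bad], small_phantom.t2_volume)


@pytest.fixture(scope="module")
def tiny_cohort():
    return [
        generate_phantom(
            PhantomSpec(image_shape=(64, 64, 12), t1_shape=(64, 64, 12),
                        plaque_depth_mm=4.0, seed=i)
        )
        for i in range(6)
    ]


class TestTraining:
    def test_loss_decreases_over_training(self, tiny_cohort):
        model = train_toy_segmenter(tiny_cohort, epochs=12, seed=0)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_deterministic_under_seed(self, tiny_cohort):
        a = train_toy_segmenter(tiny_cohort[:4], epochs=3, seed=1)
        b = train_toy_segmenter(tiny_cohort[:4], epochs=3, seed=1)
        assert abs(a.loss_history[-1] - b.loss_history[-1]) < 1e-4
        assert np.allclose(a.weights, b.weights)

    def test_zero_epochs_warns_and_returns_untrained(self, tiny_cohort):
        with pytest.warns(UserWarning):
            model = train_toy_segmenter(tiny_cohort[:4], epochs=0, seed=0)
        assert model.loss_history == []

    def test_probabilities_normalized(self, tiny_cohort):
        model = train_toy_segmenter(tiny_cohort[:4], epochs=2, seed=0)
        probs = model.predict_proba(tiny_cohort[0].t2_volume)
        assert probs.shape == (len(SEG_CLASSES),) + tiny_cohort[0].t2_volume.shape
        assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_divergence_detected(self, tiny_cohort):
        import dataclasses

        blown_up = [
            dataclasses.replace(
                s, t2_volume=s.t2_volume.copy_with(s.t2_volume.data.astype(np.float64) * 1e200)
            )
            for s in tiny_cohort[:4]
        ]
        with pytest.raises(DivergenceError):
            train_toy_segmenter(blown_up, epochs=3, seed=0, lr=1e3)

    def test_target_remap_merges_ovaries(self, tiny_cohort):
        target = organ_training_target(tiny_cohort[0])
        left = tiny_cohort[0].organ_mask.binary("ovary_left")
        right = tiny_cohort[0].organ_mask.binary("ovary_right")
        assert (target[left] == 4).all() and (target[right] == 4).all()
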