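import math

import numpy as np
import pytest

from autocontour.model import (
    AugmentBounds,
    ModelParams,
    ReduceLROnPlateau,
    augment_pair,
    build_unet,
    combined_loss,
    load_weights,
    predict_volume,
    sample_affine_params,
    save_weights,
    train,
)
from autocontour.model import _loss_and_logit_grad
from autocontour.preprocess import DEFAULT_ORGANS, TrainingSample
from conftest import make_volume


def tiny_params(**kw):
    base = dict(depth=2, base_filters=4, dropout_rate=0.25, epochs=3,
                batch_size=4, input_size=32, seed=11, lr_init=1e-3)
    base.update(kw)
    return ModelParams(**base)


def tiny_samples(n, size=32, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        img = rng.random((size, size)).astype(np.float32)
        lab = np.zeros((size, size), bool)
        r, c = rng.integers(4, size - 10, 2)
        lab[r:r + 6, c:c + 6] = True
        img[lab] = 1.0
        out.append(TrainingSample(img, lab, "organ", f"p{i}", i))
    return out


class TestCombinedLoss:
    def test_hand_computed_half_case(self):
        # dice = 1 - (2*0.5 + s)/(1 + 1 + s); bce = ln 2
        y = np.array([1.0, 0.0])
        p = np.array([0.5, 0.5])
        expected = (1.0 - (1.0 + 1e-6) / (2.0 + 1e-6)) + math.log(2.0)
        assert combined_loss(y, p) == pytest.approx(expected, abs=1e-9)
        assert combined_loss(y, p) == pytest.approx(1.1931, abs=1e-3)

    def test_perfect_prediction_near_zero(self):
        y = np.ones((16, 16))
        assert combined_loss(y, y) <= 1e-5

    def test_empty_empty_near_zero(self):
        z = np.zeros((16, 16))
        assert combined_loss(z, z) <= 1e-5

    def test_decomposition_exact(self):
        rng = np.random.default_rng(1)
        y = (rng.random((8, 8)) < 0.4).astype(float)
        p = rng.random((8, 8))
        total, dice, bce = combined_loss(y, p, return_terms=True)
        assert total == dice + bce
        assert 0.0 <= dice <= 1.0
        assert bce >= 0.0

    def test_aligned_scores_better_than_antialigned(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = (rng.random((12, 12)) < rng.uniform(0.1, 0.9)).astype(float)
            if y.min() == y.max():
                continue
            good = y * 0.9 + 0.05
            assert combined_loss(y, good) < combined_loss(y, 1.0 - good)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros(3), np.zeros(4))

    def test_training_loss_is_mean_of_per_sample_reference(self):
        rng = np.random.default_rng(3)
        y = (rng.random((2, 8, 8, 1)) < 0.3).astype(np.float32)
        p = rng.random((2, 8, 8, 1)).astype(np.float32)
        loss, _ = _loss_and_logit_grad(y, p)
        per_sample = np.mean([combined_loss(y[i], p[i]) for i in range(2)])
        assert loss == pytest.approx(per_sample, rel=1e-5)


class TestBuildUnet:
    def test_depth4_downsamples_256_to_16(self):
        params = ModelParams(depth=4, base_filters=2, seed=0)
        net = build_unet(params)
        x = np.random.default_rng(0).random((1, 256, 256, 1), dtype=np.float32)
        net.forward(x)
        bottleneck_input = net.pools[-1]._shape  # deepest pre-pool shape
        assert bottleneck_input[1] // 2 == 16

    def test_output_strictly_inside_unit_interval(self):
        net = build_unet(tiny_params())
        x = np.random.default_rng(1).random((2, 32, 32, 1), dtype=np.float32)
        p = net.forward(x)
        assert p.shape == (2, 32, 32, 1)
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_seeded_builds_are_identical(self):
        a = build_unet(tiny_params())
        b = build_unet(tiny_params())
        for (wa, _), (wb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(wa, wb)
        c = build_unet(tiny_params(seed=12))
        assert not np.array_equal(a.parameters()[0][0], c.parameters()[0][0])

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_unet(tiny_params(input_size=50))

    def test_parameter_count_deterministic(self):
        assert build_unet(tiny_params()).n_parameters() == \
            build_unet(tiny_params()).n_parameters()


class TestAugmentation:
    def test_zero_bounds_is_identity(self):
        bounds = AugmentBounds(0.0, 0.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        img = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        lab = np.zeros((64, 64), bool)
        lab[10:20, 10:20] = True
        img2, lab2 = augment_pair(img, lab, bounds, rng)
        assert np.array_equal(img, img2)
        assert np.array_equal(lab, lab2)

    def test_sampled_parameters_within_bounds(self):
        bounds = AugmentBounds()
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = sample_affine_params(bounds, rng)
            assert abs(p["rotation_deg"]) <= 10.0
            assert abs(p["translate_r_frac"]) <= 0.15
            assert abs(p["translate_c_frac"]) <= 0.15
            assert abs(p["zoom_frac"]) <= 0.10
            assert abs(p["shear_deg"]) <= 0.2

    def test_rotated_disc_conserves_area(self):
        yy, xx = np.mgrid[0:128, 0:128]
        lab = ((yy - 63.5) ** 2 + (xx - 63.5) ** 2) <= 30 ** 2
        img = lab.astype(np.float32)
        bounds = AugmentBounds(10.0, 0.0, 0.0, 0.0)
        rng = np.random.default_rng(5)
        for _ in range(5):
            _, lab2 = augment_pair(img, lab, bounds, rng)
            assert lab2.dtype == bool
            assert abs(int(lab2.sum()) - int(lab.sum())) / lab.sum() < 0.05

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            AugmentBounds(max_rotation_deg=-1.0)


class TestPlateauScheduler:
    def test_forced_plateau_sequence_and_floor(self):
        # full-scale schedule constants: 5e-5, x0.25 on plateau, floored at 1e-6
        sched = ReduceLROnPlateau(5e-5, factor=0.25, patience=1, lr_min=1e-6)
        seen = [sched.lr]
        sched.update(1.0)  # first epoch sets the best
        for _ in range(6):
            seen.append(sched.update(1.0))  # no improvement ever
        assert seen[0] == pytest.approx(5e-5)
        assert sched.lr == 1e-6
        distinct = sorted(set(seen), reverse=True)
        assert distinct == [pytest.approx(v) for v in (5e-5, 1.25e-5, 3.125e-6, 1e-6)]

    def test_improvement_resets_patience(self):
        sched = ReduceLROnPlateau(1e-3, patience=2)
        for loss in (1.0, 0.9, 0.8, 0.7):
            assert sched.update(loss) == 1e-3


class TestTrain:
    def test_loss_decreases_and_lr_floor(self):
        samples = tiny_samples(10)
        net, history = train(samples[:8], samples[8:], tiny_params(epochs=12))
        assert history.train_loss[-1] < history.train_loss[0]
        assert len(history) == 12
        assert min(history.lr) >= 1e-6
        assert all(b <= a + 1e-15 for a, b in zip(history.lr, history.lr[1:]))

    def test_seeded_training_reproducible(self):
        samples = tiny_samples(8)
        _, h1 = train(samples[:6], samples[6:], tiny_params(epochs=3))
        _, h2 = train(samples[:6], samples[6:], tiny_params(epochs=3))
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_empty_partition_rejected(self):
        samples = tiny_samples(4)
        with pytest.raises(ValueError):
            train([], samples, tiny_params())
        with pytest.raises(ValueError):
            train(samples, [], tiny_params())


class TestPredictVolume:
    def test_geometry_round_trip_and_range(self):
        params = ModelParams(depth=2, base_filters=2, seed=0, input_size=256)
        net = build_unet(params)
        vol = make_volume(shape=(3, 300, 300), spacing=(1.0, 1.0), fill=40.0)
        pred = predict_volume(net, vol, DEFAULT_ORGANS["brainstem"])
        assert pred.probs.shape == vol.shape
        assert pred.probs.min() >= 0.0 and pred.probs.max() <= 1.0
        # voxels outside the central 256x256 crop carry probability 0
        assert np.all(pred.probs[:, :22, :] == 0.0)
        assert np.all(pred.probs[:, :, 278:] == 0.0)

    def test_resampled_spacing_maps_back_to_native_grid(self):
        params = ModelParams(depth=2, base_filters=2, seed=0, input_size=256)
        net = build_unet(params)
        vol = make_volume(shape=(2, 200, 200), spacing=(1.5, 1.5), fill=0.0)
        pred = predict_volume(net, vol, DEFAULT_ORGANS["brainstem"])
        assert pred.probs.shape == (2, 200, 200)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        net = build_unet(tiny_params())
        x = np.random.default_rng(0).random((1, 32, 32, 1), dtype=np.float32)
        before = net.forward(x)
        save_weights(net, tmp_path / "organ.npz", organ="organ",
                     params=tiny_params())
        loaded, manifest = load_weights(tmp_path / "organ.npz")
        assert manifest["organ"] == "organ"
        assert np.array_equal(loaded.forward(x), before)
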