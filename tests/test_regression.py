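"""Target-map construction, loss oracle, regressor contracts, training."""

import numpy as np
import pytest

import nucadapt as na
from nucadapt.postprocess import PostprocessConfig
from nucadapt.regression import Regressor


class TestBuildTargetMap:
    def test_no_annotations_gives_zero_map(self):
        tm = na.build_target_map([], (32, 32))
        assert tm.shape == (32, 32, 3)
        assert not tm.any()

    def test_single_annotation_peaks_at_center_other_channels_zero(self):
        ann = [na.PointAnnotation(20, 11, "IPT")]
        tm = na.build_target_map(ann, (64, 64))
        ipt = tm[..., 0]
        assert np.unravel_index(np.argmax(ipt), ipt.shape) == (20, 11)
        assert ipt[20, 11] == pytest.approx(1.0)
        assert not tm[..., 1].any() and not tm[..., 2].any()

    def test_two_distant_bumps_equal_pixelwise_max_of_singles(self):
        a = na.PointAnnotation(16, 16, "INT")
        b = na.PointAnnotation(16, 48, "INT")  # 2×radius apart at default config
        joint = na.build_target_map([a, b], (64, 64))
        m1 = na.build_target_map([a], (64, 64))
        m2 = na.build_target_map([b], (64, 64))
        assert np.array_equal(joint, np.maximum(m1, m2))

    def test_local_maxima_count_matches_annotations(self):
        anns = [
            na.PointAnnotation(20, 20, "INT"),
            na.PointAnnotation(20, 60, "INT"),
            na.PointAnnotation(70, 40, "INT"),
        ]
        tm = na.build_target_map(anns, (96, 96))
        peaks = na.local_maxima(
            tm[..., 1], PostprocessConfig(neighborhood_radius=3, min_separation=10)
        )
        assert sorted(peaks) == sorted((a.row, a.col) for a in anns)

    def test_out_of_bounds_annotation_rejected(self):
        with pytest.raises(ValueError):
            na.build_target_map([na.PointAnnotation(70, 1, "NT")], (64, 64))


class TestRegressionLoss:
    def test_identity_zero_and_extremal_one(self, rng):
        y = rng.random((8, 8, 3))
        assert na.regression_loss(y, y) == 0.0
        assert na.regression_loss(np.zeros((8, 8, 3)), np.ones((8, 8, 3))) == 1.0

    def test_matches_elementwise_loop(self, rng):
        p = rng.random((8, 8, 3))
        t = rng.random((8, 8, 3))
        acc = sum(
            (float(p[i, j, c]) - float(t[i, j, c])) ** 2
            for i in range(8)
            for j in range(8)
            for c in range(3)
        )
        assert na.regression_loss(p, t) == pytest.approx(acc / 192.0, rel=1e-9)
        assert na.regression_loss(p, t) == na.regression_loss(t, p)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            na.regression_loss(np.zeros((4, 4, 3)), np.zeros((4, 5, 3)))


class TestRegressorNetwork:
    def test_output_shape_and_nonnegativity(self, rng):
        model = na.build_regressor(na.RegressorSpec(base_width=4), seed=0)
        out = model.predict(rng.random((64, 64, 3)).astype(np.float32))
        assert out.shape == (64, 64, 3)
        assert out.min() >= 0.0

    def test_arbitrary_size_padded_and_cropped(self, rng):
        model = na.build_regressor(na.RegressorSpec(base_width=4), seed=0)
        out = model.predict(rng.random((70, 90, 3)).astype(np.float32))
        assert out.shape == (70, 90, 3)

    def test_parameter_count_changes_with_fusion_and_skips(self):
        full = na.count_parameters(Regressor(na.RegressorSpec(base_width=4), 0))
        no_fuse = na.count_parameters(
            Regressor(na.RegressorSpec(base_width=4, fusion=False), 0)
        )
        no_skip = na.count_parameters(
            Regressor(na.RegressorSpec(base_width=4, skip_connections=False), 0)
        )
        assert len({full, no_fuse, no_skip}) == 3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            na.RegressorSpec(encoder_blocks=0)


class TestTrainRegressor:
    def test_single_epoch_smoke(self, small_domain_pair):
        src, _ = small_domain_pair
        model = na.train_regressor(
            src,
            [],
            na.TargetMapConfig(),
            na.RegressorSpec(base_width=4),
            na.RegressorTrainConfig(epochs=1, seed=0),
        )
        assert len(model.history["train"]) == 1
        assert len(model.history["val"]) == 1

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            na.train_regressor(
                [], [], na.TargetMapConfig(), na.RegressorSpec(), na.RegressorTrainConfig()
            )

    def test_memorization_loss_decreases(self, small_domain_pair):
        src, _ = small_domain_pair
        model = na.train_regressor(
            src[:2],
            [],
            na.TargetMapConfig(),
            na.RegressorSpec(base_width=4),
            na.RegressorTrainConfig(epochs=20, seed=1),
        )
        assert model.history["train"][-1] < model.history["train"][0]

    def test_determinism_under_seed(self, small_domain_pair):
        src, _ = small_domain_pair
        cfg = na.RegressorTrainConfig(epochs=1, seed=5)
        m1 = na.train_regressor(src[:2], [], na.TargetMapConfig(), na.RegressorSpec(base_width=4), cfg)
        m2 = na.train_regressor(src[:2], [], na.TargetMapConfig(), na.RegressorSpec(base_width=4), cfg)
        x = src[2].pixels
        assert np.array_equal(m1.predict(x), m2.predict(x))

    def test_trained_peaks_beat_random_pixel_null(self, small_domain_pair):
        src, _ = small_domain_pair
        model = na.train_regressor(
            src,
            [],
            na.TargetMapConfig(),
            na.RegressorSpec(base_width=8),
            na.RegressorTrainConfig(epochs=15, seed=2, augment=True),
        )
        rng = np.random.default_rng(0)
        margins = []
        for im in src:
            merged = na.merge_channels(model.predict(im.pixels))
            ann_vals = [merged[a.row, a.col] for a in im.annotations]
            null = merged[rng.integers(0, 64, 200), rng.integers(0, 64, 200)]
            margins.append(np.mean(ann_vals) > np.quantile(null, 0.95))
        assert np.mean(margins) >= 0.75
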