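"""Hungarian matching vs exhaustive enumeration, metric formulas, sweeps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucadapt as na
from nucadapt.evaluation import EvalConfig, curve_auc
from nucadapt.types import Detection, PointAnnotation
from oracles import brute_force_match, random_match_instance as random_instance


class TestMatch:
    def test_exact_hits_all_matched(self):
        anns = [PointAnnotation(5, 5, "IPT"), PointAnnotation(20, 20, "INT")]
        dets = [Detection(5, 5, "IPT", 1.0), Detection(20, 20, "INT", 0.5)]
        m = na.match(dets, anns, r=16)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0
        assert m.total_distance == 0.0

    def test_one_detection_two_annotations_is_one_to_one(self):
        anns = [PointAnnotation(10, 5, "IPT"), PointAnnotation(10, 15, "IPT")]
        dets = [Detection(10, 10, "IPT", 1.0)]
        m = na.match(dets, anns, r=16)
        assert m.tp == 1 and m.fp == 0 and m.fn == 1

    def test_empty_inputs(self):
        m = na.match([], [], r=16)
        assert (m.tp, m.fp, m.fn) == (0, 0, 0)

    def test_beyond_radius_is_infeasible(self):
        m = na.match([Detection(0, 0, "IPT", 1.0)], [PointAnnotation(0, 30, "IPT")], r=16)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_class_restriction_blocks_cross_label_pairs(self):
        m = na.match(
            [Detection(5, 5, "INT", 1.0)],
            [PointAnnotation(5, 5, "IPT")],
            r=16,
            class_restricted=True,
        )
        assert m.tp == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        dets, anns = random_instance(seed)
        m = na.match(dets, anns, r=16)
        card, total = brute_force_match(dets, anns, 16)
        assert m.tp == card
        assert m.total_distance == pytest.approx(total, abs=1e-9)

    def test_count_conservation(self):
        for seed in range(20):
            dets, anns = random_instance(seed)
            m = na.match(dets, anns, r=12)
            assert m.tp + m.fp == len(dets)
            assert m.tp + m.fn == len(anns)


class TestPrf:
    def test_qualitative_example_counts(self):
        p, r, f1 = na.prf(374, 30, 155)
        assert p == pytest.approx(0.9257, abs=2e-4)
        assert r == pytest.approx(0.7070, abs=2e-4)
        assert f1 == pytest.approx(0.8018, abs=2e-4)

    def test_degenerate_and_perfect(self):
        assert na.prf(0, 0, 0) == (0.0, 0.0, 0.0)
        assert na.prf(10, 0, 0) == (1.0, 1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            na.prf(-1, 0, 0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_f1_is_harmonic_mean(self, tp, fp, fn):
        p, r, f1 = na.prf(tp, fp, fn)
        expected = 2 * p * r / (p + r) if p + r else 0.0
        assert f1 == pytest.approx(expected, abs=1e-12)


class TestPixelConfusion:
    def test_true_negatives_on_inferred_grid(self):
        tn, _, _ = na.pixel_confusion(374, 30, 155, (596, 596))
        assert tn == 354_657
        tn2, _, _ = na.pixel_confusion(8, 3, 3, (596, 596))
        assert tn2 == 355_202

    def test_grid_conservation(self):
        for tp, fp, fn in [(374, 30, 155), (8, 3, 3), (199, 35, 98), (110, 49, 111)]:
            tn, _, _ = na.pixel_confusion(tp, fp, fn, (596, 596))
            assert tp + fp + fn + tn == 596 * 596

    def test_degenerate_conventions(self):
        tn, spec, sens = na.pixel_confusion(0, 0, 0, (10, 10))
        assert (tn, spec, sens) == (100, 1.0, 0.0)

    def test_counts_exceeding_grid_rejected(self):
        with pytest.raises(ValueError):
            na.pixel_confusion(90, 90, 90, (10, 10))


class TestCurveAuc:
    def test_two_point_hand_integration(self):
        assert curve_auc([(1.0, 0.5), (0.5, 1.0)]) == pytest.approx(0.875)

    def test_flat_perfect_curve(self):
        assert curve_auc([(1.0, 0.2), (1.0, 1.0)]) == pytest.approx(1.0)


class TestPrAuc:
    def test_perfect_maps_reach_unit_auc(self):
        anns = [
            [PointAnnotation(20, 20, "IPT"), PointAnnotation(20, 60, "INT")],
            [PointAnnotation(40, 40, "NT")],
        ]
        maps = [na.build_target_map(a, (96, 96)) for a in anns]
        cfg = EvalConfig(radius=8.0, eta_grid=tuple(np.linspace(0, 1, 11)))
        curve, auc = na.pr_auc(maps, anns, cfg)
        assert all(p == 1.0 for p, _ in curve)
        assert auc == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_maps_give_zero_auc(self):
        anns = [[PointAnnotation(10, 10, "IPT")]]
        maps = [np.zeros((64, 64, 3), dtype=np.float32)]
        cfg = EvalConfig(radius=8.0, eta_grid=tuple(np.linspace(0, 1, 6)))
        _, auc = na.pr_auc(maps, anns, cfg)
        assert auc == 0.0

    def test_no_annotations_rejected(self):
        cfg = EvalConfig(eta_grid=(0.0, 1.0))
        with pytest.raises(ValueError):
            na.pr_auc([np.zeros((64, 64, 3))], [[]], cfg)


class TestWeightedMetrics:
    def test_identical_metrics_invariant_to_weights(self):
        per_class = {c: (0.7, 0.6, 0.65) for c in na.CLASSES}
        out = na.weighted_classification_metrics(per_class, {"IPT": 3, "INT": 9, "NT": 1})
        assert out == pytest.approx((0.7, 0.6, 0.65))

    def test_single_class_f1_weighted_by_share(self):
        per_class = {"IPT": (1.0,), "INT": (0.0,), "NT": (0.0,)}
        counts = {"IPT": 1519, "INT": 7989, "NT": 2272}
        (wf1,) = na.weighted_classification_metrics(per_class, counts)
        assert wf1 == pytest.approx(1519 / 11780, abs=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            na.weighted_classification_metrics({"IPT": (1.0,)}, {"IPT": 0})


class TestRadiusSensitivity:
    def _jittered(self, shift):
        anns = [
            PointAnnotation(30, 30, "IPT"),
            PointAnnotation(30, 70, "INT"),
            PointAnnotation(70, 30, "NT"),
            PointAnnotation(70, 70, "INT"),
        ]
        dets = [Detection(a.row + shift, a.col, a.label, 1.0) for a in anns]
        return dets, anns

    def test_exact_detections_invariant_to_radius(self):
        dets, anns = self._jittered(0)
        f1s = [na.prf(*self._counts(dets, anns, r))[2] for r in (8, 12, 16)]
        assert f1s[0] == f1s[1] == f1s[2] == 1.0

    def test_ten_pixel_jitter_orders_radii(self):
        dets, anns = self._jittered(10)
        f1s = [na.prf(*self._counts(dets, anns, r))[2] for r in (8, 12, 16)]
        assert f1s[0] < f1s[1] <= f1s[2]

    @staticmethod
    def _counts(dets, anns, r):
        m = na.match(dets, anns, r)
        return m.tp, m.fp, m.fn

    def test_f1_nondecreasing_in_radius_random_instances(self):
        for seed in range(10):
            dets, anns = random_instance(seed, max_n=6, span=30)
            if not anns and not dets:
                continue
            f1s = []
            for r in (8, 12, 16):
                m = na.match(dets, anns, r)
                f1s.append(na.prf(m.tp, m.fp, m.fn)[2])
            assert all(a <= b + 1e-12 for a, b in zip(f1s, f1s[1:]))

    def test_table_shape_from_maps(self):
        anns = [[PointAnnotation(20, 20, "IPT"), PointAnnotation(50, 50, "INT")]]
        maps = [na.build_target_map(anns[0], (96, 96))]
        df = na.radius_sensitivity(maps, anns, EvalConfig(radius=16.0))
        assert list(df["radius"]) == [8.0, 12.0, 16.0]
        assert set(df.columns) >= {"radius", "detection_f1", "classification_f1"}
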