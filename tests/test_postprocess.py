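"""Suppression, local maxima (vs a definitional scan), detection chain."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucadapt as na
from nucadapt.postprocess import PostprocessConfig


def brute_force_maxima(values: np.ndarray, config: PostprocessConfig):
    """Definitional O(H·W·k²) re-implementation used as an oracle:
    dominance over the Euclidean disk, plateau collapse to the lexicographic
    representative, then greedy separation pruning by descending value."""
    h, w = values.shape
    r = int(np.ceil(config.neighborhood_radius))
    qualifying = []
    for i in range(h):
        for j in range(w):
            v = values[i, j]
            if v <= 0:
                continue
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di * di + dj * dj > config.neighborhood_radius**2:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and values[ni, nj] > v:
                        ok = False
            if ok:
                qualifying.append((i, j))
    # collapse 8-connected equal-valued plateaus
    qual = set(qualifying)
    seen, reps = set(), []
    for p in sorted(qualifying):
        if p in seen:
            continue
        stack, comp = [p], []
        while stack:
            q = stack.pop()
            if q in seen:
                continue
            seen.add(q)
            comp.append(q)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (q[0] + di, q[1] + dj)
                    if nb in qual and nb not in seen and values[nb] == values[q]:
                        stack.append(nb)
        reps.append(min(comp))
    reps.sort(key=lambda p: (-values[p], p[0], p[1]))
    kept = []
    for p in reps:
        if all(
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= config.min_separation**2
            for q in kept
        ):
            kept.append(p)
    return kept


class TestSuppress:
    def test_eta_zero_is_identity(self, rng):
        m = rng.random((6, 6)).astype(np.float32)
        assert np.array_equal(na.suppress(m, 0.0), m)

    def test_eta_one_keeps_only_global_max_value(self):
        m = np.array([[0.2, 0.9], [0.5, 0.9]])
        assert np.array_equal(na.suppress(m, 1.0), [[0.0, 0.9], [0.0, 0.9]])

    def test_all_zero_map_unchanged(self):
        m = np.zeros((4, 4))
        assert np.array_equal(na.suppress(m, 0.7), m)

    def test_invalid_eta_rejected(self):
        with pytest.raises(ValueError):
            na.suppress(np.ones((2, 2)), 1.5)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_idempotence(self, seed, eta):
        m = np.random.default_rng(seed).random((8, 8))
        once = na.suppress(m, eta)
        assert np.array_equal(na.suppress(once, eta), once)


class TestLocalMaxima:
    def test_single_nonzero_pixel(self):
        m = np.zeros((9, 9))
        m[4, 6] = 1.0
        assert na.local_maxima(m, PostprocessConfig()) == [(4, 6)]

    def test_two_bumps_on_9x9_grid(self):
        yy, xx = np.mgrid[0:9, 0:9]
        m = np.exp(-((yy - 2) ** 2 + (xx - 2) ** 2) / 2.0) + np.exp(
            -((yy - 2) ** 2 + (xx - 8) ** 2) / 2.0
        )
        cfg = PostprocessConfig(neighborhood_radius=2, min_separation=3)
        got = na.local_maxima(m, cfg)
        assert sorted(got) == [(2, 2), (2, 8)]
        assert got == brute_force_maxima(m, cfg)

    def test_constant_plateau_single_representative(self):
        m = np.full((9, 9), 0.5)
        assert na.local_maxima(m, PostprocessConfig()) == [(0, 0)]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_agrees_with_definitional_scan(self, seed):
        rng = np.random.default_rng(seed)
        # quantized values produce plateaus and ties
        m = np.round(rng.random((12, 12)) * 5) / 5.0
        cfg = PostprocessConfig(neighborhood_radius=2, min_separation=3)
        assert na.local_maxima(m, cfg) == brute_force_maxima(m, cfg)


class TestMergeAndClassify:
    def test_merge_single_active_channel(self, rng):
        a = rng.random((6, 6)).astype(np.float32)
        m = np.stack([a, np.zeros_like(a), np.zeros_like(a)], axis=-1)
        assert np.array_equal(na.merge_channels(m), a)

    def test_merge_takes_largest_per_pixel(self):
        m = np.zeros((2, 2, 3), dtype=np.float32)
        m[0, 0] = [0.1, 0.7, 0.3]
        assert na.merge_channels(m)[0, 0] == pytest.approx(0.7)

    def test_merged_dominates_channels(self, rng):
        m = rng.random((5, 5, 3)).astype(np.float32)
        merged = na.merge_channels(m)
        assert (merged[..., None] >= m - 1e-7).all()

    def test_classify_argmax_and_tiebreak(self):
        m = np.zeros((3, 3, 3), dtype=np.float32)
        m[1, 1] = [0.9, 0.1, 0.0]
        assert na.classify_point(m, (1, 1)) == "IPT"
        m[2, 2] = [0.4, 0.4, 0.1]
        assert na.classify_point(m, (2, 2)) == "IPT"
        m[0, 0] = [0.0, 0.2, 0.2]
        assert na.classify_point(m, (0, 0)) == "INT"

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(ValueError):
            na.classify_point(np.zeros((3, 3, 3)), (3, 0))


class TestDetect:
    def test_all_zero_map_gives_no_detections(self):
        assert na.detect(np.zeros((16, 16, 3))) == []

    def test_roundtrip_recovers_seven_annotations(self):
        anns = [
            na.PointAnnotation(20, 20, "IPT"),
            na.PointAnnotation(20, 60, "INT"),
            na.PointAnnotation(20, 100, "NT"),
            na.PointAnnotation(60, 40, "INT"),
            na.PointAnnotation(60, 80, "IPT"),
            na.PointAnnotation(100, 20, "NT"),
            na.PointAnnotation(100, 60, "INT"),
        ]
        tm = na.build_target_map(anns, (128, 128))
        dets = na.detect(tm, PostprocessConfig(eta=0.5))
        assert len(dets) == 7
        got = sorted((d.row, d.col, d.label) for d in dets)
        assert got == sorted((a.row, a.col, a.label) for a in anns)

    def test_detection_count_nonincreasing_in_eta(self, rng):
        m = rng.random((32, 32, 3)).astype(np.float32)
        counts = [
            len(na.detect(m, PostprocessConfig(eta=eta)))
            for eta in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_labels_equal_channel_argmax_at_peak(self, rng):
        m = rng.random((32, 32, 3)).astype(np.float32)
        for d in na.detect(m, PostprocessConfig(eta=0.3)):
            assert d.label == na.CLASSES[int(np.argmax(m[d.row, d.col]))]

    def test_detection_and_classification_modes_share_centers(self, rng):
        m = rng.random((32, 32, 3)).astype(np.float32)
        det = na.detect(m, PostprocessConfig(eta=0.4), mode="detection")
        cls = na.detect(m, PostprocessConfig(eta=0.4), mode="classification")
        assert [(d.row, d.col, d.label) for d in det] == [
            (d.row, d.col, d.label) for d in cls
        ]
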