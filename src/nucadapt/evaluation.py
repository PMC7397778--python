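"""Quantitative evaluation of point detections against point annotations.

A detection counts as a true positive only inside the gold-standard area —
a circle of radius r (default 16 px) around an annotated center — and the
pairing is a one-to-one assignment computed with the Hungarian algorithm:
maximum cardinality first, minimum total Euclidean distance among those.
Precision, recall and F1 follow P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); the PR curve is swept over the suppression fraction η and
integrated by the trapezoidal rule over recall. Classification metrics are
computed per class with class-restricted matching and aggregated by
annotation-count weights; pixel-grid confusion statistics (TN, specificity,
sensitivity) treat every pixel of the evaluation grid as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .postprocess import PostprocessConfig, detect
from .types import CLASSES, Detection, PointAnnotation


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol settings."""

    radius: float = 16.0
    eta_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 101))
    radii: tuple[float, ...] = (8.0, 12.0, 16.0)
    eta_report: float = 0.5
    class_restricted: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0 or any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        grid = np.asarray(self.eta_grid)
        if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
            raise ValueError("eta grid must lie within [0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("eta grid must be strictly increasing")


@dataclass
class MatchResult:
    """One-to-one association outcome: TP pairs, FP detections, FN annotations."""

    pairs: list[tuple[int, int, float]]
    fp_indices: list[int]
    fn_indices: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)

    @property
    def total_distance(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


def match(
    detections: list[Detection],
    annotations: list[PointAnnotation],
    r: float,
    class_restricted: bool = False,
) -> MatchResult:
    """Optimal one-to-one assignment within gold-standard circles.

    Pairs farther apart than ``r`` (or with differing labels when
    ``class_restricted``) are infeasible. Among assignments the matching
    maximizes cardinality first, then minimizes total matched distance.
    Unmatched detections become FPs; unmatched annotations FNs.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    nd, na = len(detections), len(annotations)
    if nd == 0 or na == 0:
        return MatchResult([], list(range(nd)), list(range(na)))
    dpos = np.array([[d.row, d.col] for d in detections], dtype=float)
    apos = np.array([[a.row, a.col] for a in annotations], dtype=float)
    dist = np.sqrt(((dpos[:, None, :] - apos[None, :, :]) ** 2).sum(-1))
    feasible = dist <= r
    if class_restricted:
        dlab = np.array([d.label for d in detections])
        alab = np.array([a.label for a in annotations])
        feasible &= dlab[:, None] == alab[None, :]
    # sentinel exceeding any total feasible distance ⇒ cardinality-first
    big = r * (min(nd, na) + 1) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    ]
    matched_d = {i for i, _, _ in pairs}
    matched_a = {j for _, j, _ in pairs}
    return MatchResult(
        pairs,
        [i for i in range(nd) if i not in matched_d],
        [j for j in range(na) if j not in matched_a],
    )


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 with the all-zero conventions."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def pixel_confusion(
    tp: int, fp: int, fn: int, grid: tuple[int, int]
) -> tuple[int, float, float]:
    """TN count, specificity and sensitivity on a pixel grid.

    Every pixel that is neither a TP, FP nor FN detection/annotation site
    counts as a true negative, so TN = H·W − TP − FP − FN.
    """
    h, w = grid
    total = h * w
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp + fn > total:
        raise ValueError("counts exceed the pixel grid size")
    tn = total - tp - fp - fn
    specificity = tn / (tn + fp) if tn + fp else 1.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return tn, specificity, sensitivity


# ---------------------------------------------------------------------------
# pooled counting and PR sweeps
# ---------------------------------------------------------------------------


def _pooled_counts(
    per_image_detections: list[list[Detection]],
    per_image_annotations: list[list[PointAnnotation]],
    r: float,
    class_restricted: bool,
    class_label: str | None = None,
) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for dets, anns in zip(per_image_detections, per_image_annotations):
        if class_label is not None:
            dets = [d for d in dets if d.label == class_label]
            anns = [a for a in anns if a.label == class_label]
        m = match(dets, anns, r, class_restricted=class_restricted)
        tp += m.tp
        fp += m.fp
        fn += m.fn
    return tp, fp, fn


def pr_auc(
    maps: list[np.ndarray],
    annotations: list[list[PointAnnotation]],
    config: EvalConfig,
    mode: str = "detection",
    class_label: str | None = None,
    postprocess: PostprocessConfig = PostprocessConfig(),
) -> tuple[list[tuple[float, float]], float]:
    """PR curve over the η sweep, pooled over images, and its AUC.

    ``mode='detection'`` matches irrespective of labels; with
    ``mode='classification'`` a ``class_label`` restricts detections and
    annotations to one class. The curve is sorted by recall, anchored at
    (P of the lowest-recall point, R = 0), and integrated trapezoidally;
    a sweep with no annotations in scope has undefined recall and raises.
    """
    if mode not in ("detection", "classification"):
        raise ValueError("mode must be 'detection' or 'classification'")
    if mode == "classification" and class_label is None:
        raise ValueError("classification sweeps need a class_label")
    n_ann = sum(
        1
        for anns in annotations
        for a in anns
        if class_label is None or a.label == class_label
    )
    if n_ann == 0:
        raise ValueError("no annotations in scope: recall is undefined")
    restricted = mode == "classification" and config.class_restricted
    points = []
    for eta in config.eta_grid:
        pp = PostprocessConfig(
            eta=float(eta),
            neighborhood_radius=postprocess.neighborhood_radius,
            min_separation=postprocess.min_separation,
            per_channel_suppression=postprocess.per_channel_suppression,
        )
        dets = [detect(m, pp, mode=mode) for m in maps]
        tp, fp, fn = _pooled_counts(dets, annotations, config.radius, restricted, class_label)
        p, r, _ = prf(tp, fp, fn)
        points.append((p, r))
    return points, curve_auc(points)


def curve_auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under a (precision, recall) point set.

    Points are sorted by recall; the curve is anchored at R = 0 with the
    precision of the lowest-recall point.
    """
    pts = sorted(points, key=lambda t: t[1])
    recalls = [0.0] + [r for _, r in pts]
    precisions = [pts[0][0]] + [p for p, _ in pts]
    return float(np.trapezoid(precisions, recalls))


def weighted_classification_metrics(
    per_class: dict[str, tuple[float, ...]], class_counts: dict[str, int]
) -> tuple[float, ...]:
    """Weighted arithmetic mean of per-class metric tuples.

    Weights are the class shares of annotations in the test set,
    count_c / Σ counts.
    """
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("at least one class count must be positive")
    lengths = {len(v) for v in per_class.values()}
    if len(lengths) != 1:
        raise ValueError("per-class metric tuples must have equal length")
    k = lengths.pop()
    out = []
    for i in range(k):
        out.append(
            sum(per_class[c][i] * class_counts.get(c, 0) for c in per_class) / total
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Full evaluation of a set of predicted maps on annotated images."""

    detection: dict
    per_class: dict[str, dict]
    weighted: dict
    pixel: dict
    class_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "detection": self.detection,
            "per_class": self.per_class,
            "weighted": self.weighted,
            "pixel": self.pixel,
            "class_counts": self.class_counts,
        }


def evaluate_maps(
    maps: list[np.ndarray],
    annotations: list[list[PointAnnotation]],
    config: EvalConfig = EvalConfig(),
    postprocess: PostprocessConfig = PostprocessConfig(),
    sweep: bool = True,
) -> MetricsReport:
    """Complete protocol: point metrics at ``eta_report``, optional AUC sweep,
    weighted multiclass aggregation and pixel-grid confusion statistics."""
    pp = PostprocessConfig(
        eta=config.eta_report,
        neighborhood_radius=postprocess.neighborhood_radius,
        min_separation=postprocess.min_separation,
        per_channel_suppression=postprocess.per_channel_suppression,
    )
    dets = [detect(m, pp, mode="detection") for m in maps]
    class_counts = {
        c: sum(sum(a.label == c for a in anns) for anns in annotations) for c in CLASSES
    }
    grid_pixels = int(sum(m.shape[0] * m.shape[1] for m in maps))

    tp, fp, fn = _pooled_counts(dets, annotations, config.radius, False)
    p, r, f1 = prf(tp, fp, fn)
    tn, spec, sens = pixel_confusion(tp, fp, fn, (grid_pixels, 1))
    detection = {"tp": tp, "fp": fp, "fn": fn, "precision": p, "recall": r, "f1": f1}
    pixel = {
        "detection": {"tn": tn, "specificity": spec, "sensitivity": sens},
        "grid_pixels": grid_pixels,
    }
    if sweep:
        _, auc = pr_auc(maps, annotations, config, "detection", postprocess=postprocess)
        detection["auc"] = auc

    per_class: dict[str, dict] = {}
    for c in CLASSES:
        ctp, cfp, cfn = _pooled_counts(
            dets, annotations, config.radius, config.class_restricted, c
        )
        cp, cr, cf1 = prf(ctp, cfp, cfn)
        entry = {"tp": ctp, "fp": cfp, "fn": cfn, "precision": cp, "recall": cr, "f1": cf1}
        ctn, cspec, csens = pixel_confusion(ctp, cfp, cfn, (grid_pixels, 1))
        pixel[c] = {"tn": ctn, "specificity": cspec, "sensitivity": csens}
        if sweep and class_counts[c] > 0:
            _, cauc = pr_auc(
                maps, annotations, config, "classification", c, postprocess=postprocess
            )
            entry["auc"] = cauc
        per_class[c] = entry

    keys = ["precision", "recall", "f1"] + (["auc"] if sweep else [])
    present = {c: per_class[c] for c in CLASSES if class_counts[c] > 0}
    weighted_vals = weighted_classification_metrics(
        {c: tuple(present[c].get(k, 0.0) for k in keys) for c in present},
        {c: class_counts[c] for c in present},
    )
    weighted = dict(zip(keys, weighted_vals))
    return MetricsReport(detection, per_class, weighted, pixel, class_counts)


def radius_sensitivity(
    maps: list[np.ndarray],
    annotations: list[list[PointAnnotation]],
    config: EvalConfig = EvalConfig(),
    postprocess: PostprocessConfig = PostprocessConfig(),
) -> pd.DataFrame:
    """F1 per gold-standard radius for detection and weighted classification.

    For a fixed detection set, growing r only adds feasible pairs, so F1 is
    non-decreasing in r.
    """
    pp = PostprocessConfig(
        eta=config.eta_report,
        neighborhood_radius=postprocess.neighborhood_radius,
        min_separation=postprocess.min_separation,
        per_channel_suppression=postprocess.per_channel_suppression,
    )
    dets = [detect(m, pp, mode="detection") for m in maps]
    class_counts = {
        c: sum(sum(a.label == c for a in anns) for anns in annotations) for c in CLASSES
    }
    rows = []
    for r in config.radii:
        tp, fp, fn = _pooled_counts(dets, annotations, r, False)
        _, _, f1_det = prf(tp, fp, fn)
        per_class_f1 = {}
        for c in CLASSES:
            if class_counts[c] == 0:
                continue
            ctp, cfp, cfn = _pooled_counts(dets, annotations, r, config.class_restricted, c)
            per_class_f1[c] = prf(ctp, cfp, cfn)[2]
        (wf1,) = weighted_classification_metrics(
            {c: (v,) for c, v in per_class_f1.items()},
            {c: class_counts[c] for c in per_class_f1},
        )
        rows.append({"radius": r, "detection_f1": f1_det, "classification_f1": wf1})
    return pd.DataFrame(rows)
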