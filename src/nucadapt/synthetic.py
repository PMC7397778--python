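"""Synthetic two-domain Ki-67-like image generator.

Real inter-institutional Ki-67 IHC datasets are rarely shareable, so this
module generates image pairs that emulate their essential structure: clustered
elliptical nuclei of three classes distinguishable by color (DAB-brown
immunopositive tumor, hematoxylin-blue immunonegative tumor, and smaller
blue-gray nontumor nuclei) over a textured background, with a systematic
global color/contrast shift between a "source" and a "target" style standing
in for scanner and staining variability between institutions.

Every operation is a pure function of its parameters and an integer seed;
ground-truth point annotations are exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import CLASSES, AnnotatedImage, PointAnnotation


class InfeasibleLayoutError(RuntimeError):
    """Raised when rejection sampling cannot place all requested nuclei."""


@dataclass(frozen=True)
class StyleParams:
    """Rendering style of one imaging domain.

    The inter-domain appearance shift is a global color transform applied
    after rendering: a contrast change about mid-gray, a hue rotation about
    the gray axis (``hue_rotation_deg``, the channel-mixing component that
    models differing stain/scanner color responses), and an additive
    per-channel offset ``hue_shift``. The per-nucleus ``jitter`` and
    background ``texture`` amplitudes model within-domain variability.
    """

    background: tuple[float, float, float] = (0.93, 0.91, 0.88)
    class_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "IPT": (0.48, 0.28, 0.12),  # DAB brown
            "INT": (0.23, 0.28, 0.62),  # hematoxylin blue
            "NT": (0.45, 0.50, 0.62),  # pale blue-gray
        }
    )
    jitter: float = 0.03
    texture: float = 0.02
    hue_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hue_rotation_deg: float = 0.0
    contrast: float = 1.0
    #: expected count (per 64×64 tile area) of small sharp hematoxylin-tinted
    #: debris spots — lymphocyte-like dots a nucleus detector must learn to
    #: reject; 0 disables
    clutter: float = 0.0
    clutter_color: tuple[float, float, float] = (0.40, 0.40, 0.50)
    clutter_radius: tuple[float, float] = (1.0, 1.8)

    def __post_init__(self) -> None:
        for v in (*self.background, *(c for col in self.class_colors.values() for c in col)):
            if not 0.0 <= v <= 1.0:
                raise ValueError("colors must lie in [0, 1]")
        if self.jitter < 0 or self.texture < 0 or self.clutter < 0:
            raise ValueError("jitter, texture and clutter amplitudes must be >= 0")
        if set(self.class_colors) != set(CLASSES):
            raise ValueError(f"class_colors must cover {CLASSES}")


@dataclass(frozen=True)
class LayoutParams:
    """Geometry of one synthetic tile: counts, sizes and spacing of nuclei."""

    height: int = 64
    width: int = 64
    n_ipt: int = 2
    n_int: int = 4
    n_nt: int = 2
    radius_range: tuple[float, float] = (3.0, 5.0)
    min_separation: float = 10.0
    clustering: float = 0.5

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("images must be at least 64×64")
        if min(self.n_ipt, self.n_int, self.n_nt) < 0:
            raise ValueError("counts must be >= 0")
        if self.radius_range[0] < 2:
            raise ValueError("minimum nucleus radius must be >= 2 px")
        if self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius range must be (min, max) with min <= max")
        if self.min_separation <= 0:
            raise ValueError("minimum separation must be positive")
        if self.clustering < 0:
            raise ValueError("clustering strength must be >= 0")
        # crude feasibility bound: each point excludes a disk of sep/2
        n = self.n_ipt + self.n_int + self.n_nt
        area = self.height * self.width
        if n * math.pi * (self.min_separation / 2.0) ** 2 > area:
            raise ValueError("requested counts cannot be packed into the image area")

    @property
    def total(self) -> int:
        return self.n_ipt + self.n_int + self.n_nt


def default_source_style() -> StyleParams:
    """Source-domain style: clean light background, no global shift."""
    return StyleParams()


def default_target_style() -> StyleParams:
    """Target-domain style: a different institution's stain/scanner response.

    Weaker hematoxylin (pale, low-contrast INT and NT nuclei on a darker,
    lavender background) with DAB-brown IPT still prominent, plus a global
    hue rotation, mild contrast change, stronger texture and nucleus-scale
    stain clutter — the severe appearance variability that motivates
    adapting rather than reusing a source-trained model.
    """
    return StyleParams(
        background=(0.64, 0.58, 0.72),
        class_colors={
            "IPT": (0.35, 0.22, 0.12),
            "INT": (0.52, 0.50, 0.70),
            "NT": (0.58, 0.54, 0.68),
        },
        jitter=0.04,
        texture=0.05,
        hue_shift=(-0.03, 0.02, 0.06),
        hue_rotation_deg=15.0,
        contrast=1.1,
    )


# ---------------------------------------------------------------------------
# layout sampling
# ---------------------------------------------------------------------------

_ATTEMPTS_PER_POINT = 1000


def sample_layout(params: LayoutParams, seed: int) -> list[PointAnnotation]:
    """Sample nucleus centers by rejection with a minimum-separation constraint.

    With probability proportional to ``params.clustering`` a candidate is
    proposed near an already placed nucleus instead of uniformly, which
    produces the clustered arrangements typical of tumor nests. Raises
    :class:`InfeasibleLayoutError` if the attempt budget
    (1000 × total count) is exhausted.
    """
    rng = np.random.default_rng(seed)
    margin = params.radius_range[1]
    labels = (
        ["IPT"] * params.n_ipt + ["INT"] * params.n_int + ["NT"] * params.n_nt
    )
    if not labels:
        return []
    order = rng.permutation(len(labels))
    placed: list[tuple[float, float]] = []
    out_labels: list[str] = []
    budget = _ATTEMPTS_PER_POINT * len(labels)
    p_cluster = params.clustering / (1.0 + params.clustering)
    attempts = 0
    for idx in order:
        while True:
            attempts += 1
            if attempts > budget:
                raise InfeasibleLayoutError(
                    f"could not place {len(labels)} nuclei with separation "
                    f"{params.min_separation} in {params.height}×{params.width}"
                )
            if placed and rng.random() < p_cluster:
                anchor = placed[rng.integers(len(placed))]
                r, c = rng.normal(anchor, 4.0 * params.min_separation, size=2)
            else:
                r = rng.uniform(margin, params.height - 1 - margin)
                c = rng.uniform(margin, params.width - 1 - margin)
            if not (margin <= r <= params.height - 1 - margin):
                continue
            if not (margin <= c <= params.width - 1 - margin):
                continue
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= params.min_separation**2
                for pr, pc in placed
            ):
                placed.append((r, c))
                out_labels.append(labels[idx])
                break
    return [
        PointAnnotation(row=int(round(r)), col=int(round(c)), label=lab)
        for (r, c), lab in zip(placed, out_labels)
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_image(
    layout: list[PointAnnotation],
    style: StyleParams,
    dims: tuple[int, int],
    seed: int,
    case_id: str = "synthetic",
    radius_range: tuple[float, float] = (3.0, 5.0),
) -> AnnotatedImage:
    """Render a layout as an RGB tile; the layout is attached unchanged.

    Each nucleus is a filled, anti-aliased ellipse in its class color plus
    per-nucleus color jitter; NT nuclei are drawn smaller and more elongated
    than tumor nuclei. The background carries smoothed multiplicative
    texture noise, and the style's global hue/contrast shift is applied last.
    """
    h, w = dims
    for a in layout:
        if not (0 <= a.row < h and 0 <= a.col < w):
            raise ValueError(f"annotation {a} outside {h}×{w} image")
    rng = np.random.default_rng(seed)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = style.background
    if style.texture > 0:
        noise = rng.standard_normal((h, w))
        noise = ndimage.gaussian_filter(noise, sigma=2.0)
        img += style.texture * noise[..., None]
    if style.clutter > 0:
        n_spots = rng.poisson(style.clutter * h * w / 4096.0)
        spot_color = np.asarray(style.clutter_color)
        centers = np.array([[a.row, a.col] for a in layout], dtype=float).reshape(-1, 2)
        placed = 0
        attempts = 0
        while placed < n_spots and attempts < 50 * max(1, n_spots):
            attempts += 1
            sr, sc = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
            # debris sits in stroma, clear of annotated nuclei (and of the
            # gold-standard matching radius used at this tile scale)
            if centers.size and np.min(np.hypot(centers[:, 0] - sr, centers[:, 1] - sc)) < 10.0:
                continue
            placed += 1
            rad = rng.uniform(*style.clutter_radius)
            lo_r, hi_r = int(max(0, sr - rad - 2)), int(min(h, sr + rad + 3))
            lo_c, hi_c = int(max(0, sc - rad - 2)), int(min(w, sc + rad + 3))
            yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c].astype(np.float64)
            d = np.sqrt(((yy - sr) / rad) ** 2 + ((xx - sc) / rad) ** 2)
            alpha = np.clip((1.15 - d) / 0.3, 0.0, 1.0)
            img[lo_r:hi_r, lo_c:hi_c] = (
                img[lo_r:hi_r, lo_c:hi_c] * (1.0 - alpha[..., None])
                + alpha[..., None] * spot_color
            )

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    for a in layout:
        base = np.asarray(style.class_colors[a.label])
        color = np.clip(base + rng.normal(0.0, style.jitter, size=3), 0.0, 1.0)
        radius = rng.uniform(*_radius_range_for(a.label, radius_range))
        # per-class morphology: tumor nuclei near-round, NT elongated
        aspect = rng.uniform(0.45, 0.6) if a.label == "NT" else rng.uniform(0.75, 1.0)
        theta = rng.uniform(0.0, math.pi)
        dr, dc = rows - a.row, cols - a.col
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        d2 = (u / radius) ** 2 + (v / (radius * aspect)) ** 2
        # soft edge over ~1 px for anti-aliasing
        alpha = np.clip((1.15 - np.sqrt(d2)) / 0.3, 0.0, 1.0)
        img = img * (1.0 - alpha[..., None]) + alpha[..., None] * color

    img = (img - 0.5) * style.contrast + 0.5
    if style.hue_rotation_deg:
        img = img @ _hue_rotation_matrix(style.hue_rotation_deg).T
    img = img + np.asarray(style.hue_shift)
    img = np.clip(img, 0.0, 1.0)
    return AnnotatedImage(pixels=img.astype(np.float32), annotations=list(layout), case_id=case_id)


def _hue_rotation_matrix(deg: float) -> np.ndarray:
    """Rotation about the gray axis (1,1,1)/√3 — hue change at constant luma."""
    theta = np.deg2rad(deg)
    axis = np.ones(3) / np.sqrt(3.0)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def _radius_range_for(label: str, base: tuple[float, float]) -> tuple[float, float]:
    if label == "NT":
        return (base[0] * 0.8, base[1] * 0.8)
    return base


def render_layout(
    params: LayoutParams, style: StyleParams, seed: int, case_id: str
) -> AnnotatedImage:
    """Sample a layout and render it; one seed drives both stages."""
    ss = np.random.SeedSequence(seed)
    s_layout, s_render = ss.spawn(2)
    layout = sample_layout(params, int(s_layout.generate_state(1)[0] % 2**31))
    return render_image(
        layout,
        style,
        (params.height, params.width),
        int(s_render.generate_state(1)[0] % 2**31),
        case_id=case_id,
        radius_range=params.radius_range,
    )


# ---------------------------------------------------------------------------
# paired-domain dataset construction
# ---------------------------------------------------------------------------


def make_domain_datasets(
    layout: LayoutParams,
    style_source: StyleParams,
    style_target: StyleParams,
    n_source: int,
    n_target: int,
    seed: int,
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Generate a source and a target image collection with exact ground truth.

    Both collections keep their annotations — withholding target labels is
    the workflow's job, not the generator's. The two styles must differ in at
    least one field, otherwise there is no domain shift to adapt to.
    """
    if style_source == style_target:
        raise ValueError("style_source and style_target must differ in at least one field")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_source + n_target)
    source = [
        render_layout(layout, style_source, int(children[i].generate_state(1)[0] % 2**31), f"src_{i:03d}")
        for i in range(n_source)
    ]
    target = [
        render_layout(
            layout,
            style_target,
            int(children[n_source + j].generate_state(1)[0] % 2**31),
            f"tgt_{j:03d}",
        )
        for j in range(n_target)
    ]
    return source, target


def domain_classifier_accuracy(
    source: list[AnnotatedImage], target: list[AnnotatedImage]
) -> float:
    """Leave-one-out 1-nearest-centroid accuracy on mean image color.

    Measures how separable the two domains are from global color statistics
    alone; the translation stage is expected to drive this toward chance.
    """
    feats = np.array([im.pixels.mean(axis=(0, 1)) for im in source + target])
    y = np.array([0] * len(source) + [1] * len(target))
    correct = 0
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        c0 = feats[mask & (y == 0)].mean(axis=0)
        c1 = feats[mask & (y == 1)].mean(axis=0)
        pred = 0 if np.linalg.norm(feats[i] - c0) <= np.linalg.norm(feats[i] - c1) else 1
        correct += pred == y[i]
    return correct / len(y)
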