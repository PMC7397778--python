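"""From response maps to discrete nucleus detections.

The rule chain: merge the three class channels by pixelwise maximum, suppress
pixels below η·max of the merged map, find local maxima as nucleus centers,
and label each center by the argmax over the three channels at that pixel
(ties broken by the fixed priority IPT > INT > NT). A per-channel
suppression variant (suppress each channel, then merge) is available behind
a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import CLASSES, Detection, validate_output_map


@dataclass(frozen=True)
class PostprocessConfig:
    """Peak-extraction settings.

    ``eta`` is the suppression fraction of the map maximum; the neighborhood
    radius defines the Euclidean disk a peak must dominate; peaks closer
    than ``min_separation`` are pruned in descending-score order.
    """

    eta: float = 0.5
    neighborhood_radius: float = 3.0
    min_separation: float = 5.0
    per_channel_suppression: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood radius must be >= 1 px")
        if self.min_separation <= 0:
            raise ValueError("minimum separation must be positive")


def suppress(channel: np.ndarray, eta: float) -> np.ndarray:
    """Zero out values below η·max(channel); an all-zero map passes through."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    channel = np.asarray(channel)
    peak = channel.max() if channel.size else 0.0
    if peak <= 0:
        return channel.copy()
    out = channel.copy()
    out[channel < eta * peak] = 0.0
    return out


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


def local_maxima(values: np.ndarray, config: PostprocessConfig) -> list[tuple[int, int]]:
    """Strictly positive local maxima, deduplicated and separation-pruned.

    A pixel qualifies if its value is ≥ every neighbor within the Euclidean
    neighborhood radius and > 0. Connected plateaus of equal value collapse
    to their lexicographically smallest pixel. Survivors are ordered by
    descending value (ties by (row, col)) and greedily pruned so returned
    points are pairwise ≥ ``min_separation`` apart.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("local_maxima expects a 2-D map")
    if values.size == 0 or values.max() <= 0:
        return []
    foot = _disk_footprint(config.neighborhood_radius)
    dil = ndimage.maximum_filter(values, footprint=foot, mode="constant", cval=-np.inf)
    mask = (values >= dil) & (values > 0)
    if not mask.any():
        return []
    # collapse plateaus: adjacent qualifying pixels share their value
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    candidates: list[tuple[float, int, int]] = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        i = np.lexsort((cols, rows))[0]
        candidates.append((float(values[rows[i], cols[i]]), int(rows[i]), int(cols[i])))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[int, int]] = []
    min_sep2 = config.min_separation**2
    for _, r, c in candidates:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep2 for kr, kc in kept):
            kept.append((r, c))
    return kept


def merge_channels(output_map: np.ndarray) -> np.ndarray:
    """Pixelwise maximum across the three class channels."""
    output_map = validate_output_map(output_map)
    return output_map.max(axis=2)


def classify_point(output_map: np.ndarray, point: tuple[int, int]) -> str:
    """Label of the largest channel at a pixel; ties favor IPT, then INT."""
    output_map = validate_output_map(output_map)
    r, c = point
    h, w = output_map.shape[:2]
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"point {point} outside {h}×{w} map")
    return CLASSES[int(np.argmax(output_map[r, c]))]


def detect(
    output_map: np.ndarray,
    config: PostprocessConfig = PostprocessConfig(),
    mode: str = "detection",
) -> list[Detection]:
    """Full post-processing chain: suppress → local maxima → label.

    ``mode`` is "detection" or "classification"; both share the same centers
    from the merged map (suppression per merged map by default, per channel
    when ``config.per_channel_suppression``) and both attach channel-argmax
    labels. Output is sorted by descending score, ties by (row, col).
    """
    if mode not in ("detection", "classification"):
        raise ValueError("mode must be 'detection' or 'classification'")
    output_map = validate_output_map(output_map)
    if config.per_channel_suppression:
        sup = np.stack(
            [suppress(output_map[..., k], config.eta) for k in range(3)], axis=-1
        )
        merged = sup.max(axis=2)
    else:
        merged = suppress(merge_channels(output_map), config.eta)
    peaks = local_maxima(merged, config)
    detections = [
        Detection(
            row=r,
            col=c,
            label=classify_point(output_map, (r, c)),
            score=float(merged[r, c]),
        )
        for r, c in peaks
    ]
    detections.sort(key=lambda d: (-d.score, d.row, d.col))
    return detections
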