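"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np

from nucadapt.types import Detection, PointAnnotation
import nucadapt as na


def brute_force_match(dets, anns, r, class_restricted=False):
    """All injective assignments; maximize cardinality, then minimize total
    distance. Exponential, for instances of at most ~6 points per side."""
    nd, n_ann = len(dets), len(anns)
    feasible = {}
    for i, d in enumerate(dets):
        for j, a in enumerate(anns):
            dist = np.hypot(d.row - a.row, d.col - a.col)
            if dist <= r and (not class_restricted or d.label == a.label):
                feasible[(i, j)] = dist
    best = (0, 0.0)
    found = False
    for size in range(min(nd, n_ann), 0, -1):
        for d_sub in itertools.combinations(range(nd), size):
            for a_perm in itertools.permutations(range(n_ann), size):
                pairs = list(zip(d_sub, a_perm))
                if all(p in feasible for p in pairs):
                    total = sum(feasible[p] for p in pairs)
                    if not found or total < best[1]:
                        best = (size, total)
                        found = True
        if found:
            break
    return best


def random_match_instance(seed, max_n=6, span=40):
    rng = np.random.default_rng(seed)
    nd, n_ann = rng.integers(0, max_n + 1, 2)
    labels = list(na.CLASSES)
    dets = [
        Detection(int(r), int(c), labels[rng.integers(3)], 1.0)
        for r, c in rng.integers(0, span, (nd, 2))
    ]
    anns = [
        PointAnnotation(int(r), int(c), labels[rng.integers(3)])
        for r, c in rng.integers(0, span, (n_ann, 2))
    ]
    return dets, anns
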