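"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration over
pixels or id pairs, exact rational arithmetic) and share no code with
the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest


def brute_force_voronoi(seeds: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-seed-component assignment, smaller id on ties.

    Squared Euclidean distances are integers, so tie detection is exact.
    """
    h, w = seeds.shape
    ids = sorted(int(i) for i in np.unique(seeds) if i > 0)
    coords = {i: np.argwhere(seeds == i) for i in ids}
    out = np.zeros((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            best_id, best_d2 = 0, None
            for i in ids:  # ascending: strict < keeps the smaller id on ties
                pts = coords[i]
                d2 = int(((pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2).min())
                if best_d2 is None or d2 < best_d2:
                    best_id, best_d2 = i, d2
            out[r, c] = best_id
    return out


def brute_force_mutual_best(gt: np.ndarray, est: np.ndarray):
    """Exhaustive mutual-best matching over all (gt, est) id pairs.

    Evaluates the restricted-IoU definition literally with exact
    Fractions: a pair is matched iff its IoU is positive and strictly
    greater than every other entry in its row and its column.
    """
    gt_ids = sorted(int(i) for i in np.unique(gt) if i > 0)
    est_ids = sorted(int(i) for i in np.unique(est) if i > 0)
    iou = {}
    for g in gt_ids:
        gm = gt == g
        for e in est_ids:
            em = est == e
            inter = int(np.count_nonzero(gm & em))
            union = int(np.count_nonzero(gm | em))
            iou[(g, e)] = Fraction(inter, union) if union else Fraction(0)
    pairs = []
    for g in gt_ids:
        for e in est_ids:
            v = iou[(g, e)]
            if v == 0:
                continue
            row_ok = all(v > iou[(g, e2)] for e2 in est_ids if e2 != e)
            col_ok = all(v > iou[(g2, e)] for g2 in gt_ids if g2 != g)
            if row_ok and col_ok:
                pairs.append((g, e, float(v)))
    return sorted(pairs)


def random_instance_map(
    rng: np.random.Generator,
    shape: tuple[int, int],
    max_nuclei: int,
    max_extent: int = 8,
) -> np.ndarray:
    """Random rectangles stamped in order (later overwrite earlier), normalized."""
    from nucleifuse import normalize_ids

    h, w = shape
    out = np.zeros(shape, dtype=np.int64)
    n = int(rng.integers(0, max_nuclei + 1))
    for i in range(1, n + 1):
        hh = int(rng.integers(1, max_extent + 1))
        ww = int(rng.integers(1, max_extent + 1))
        r0 = int(rng.integers(0, max(1, h - hh + 1)))
        c0 = int(rng.integers(0, max(1, w - ww + 1)))
        out[r0 : r0 + hh, c0 : c0 + ww] = i
    return normalize_ids(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def square_nucleus():
    """A single 5x5 square nucleus centered in a 9x9 field."""
    m = np.zeros((9, 9), dtype=np.int64)
    m[2:7, 2:7] = 1
    return m


@pytest.fixture
def asymmetric_map():
    """Orientation fixture: id 1 hugs the top-left corner, id 2 bottom-right."""
    m = np.zeros((8, 12), dtype=np.int64)
    m[0:2, 0:3] = 1
    m[6:8, 9:12] = 2
    return m
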