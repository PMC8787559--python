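"""IoU*-matched F1 evaluation of instance segmentations.

Ground-truth and estimated nuclei are matched one-to-one by *mutual
best* IoU: a pair (g, e) is matched iff its IoU is positive and strictly
the largest in both its row and its column of the pairwise IoU matrix.
The restricted overlap IoU* equals the pair's IoU for matched pairs and
0 otherwise, so no nucleus is ever associated with more than one partner;
exact ties produce no match. Because IoUs are ratios of pixel counts,
strict-maximum checks are done with exact integer cross-multiplication,
never floating point, so tie handling is deterministic.

From a matching, detection/localization quality is summarized as a curve
over IoU thresholds t:

    TP(t) = #{matched pairs with IoU* > t},   FN(t) = n_gt - TP(t),
    FP(t) = n_est - TP(t),   F1(t) = 2 TP / (2 TP + FN + FP).

At t = 0.05 the curve measures detection (is each nucleus found at all);
toward t = 0.9 it measures contour localization. Curves from several
images are aggregated per-threshold as mean and population standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .labelcodec import _as_instance_array


@dataclass(frozen=True)
class Matching:
    """One-to-one mutual-best pairing of ground-truth and estimated nuclei.

    ``pairs`` holds (gt_id, est_id, iou_star) triples with iou_star > 0;
    each gt id and each est id appears at most once.
    """

    pairs: tuple[tuple[int, int, float], ...]
    n_gt: int
    n_est: int

    def __post_init__(self):
        gt_ids = [p[0] for p in self.pairs]
        est_ids = [p[1] for p in self.pairs]
        if len(set(gt_ids)) != len(gt_ids) or len(set(est_ids)) != len(est_ids):
            raise ValueError("matching is not one-to-one")
        if any(p[2] <= 0 for p in self.pairs):
            raise ValueError("matched pairs must have iou_star > 0")

    @property
    def iou_values(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=np.float64)


@dataclass(frozen=True)
class EvalCurve:
    """TP/FN/FP counts and F1 as functions of the IoU* threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray
    f1: np.ndarray
    n_gt: int
    n_est: int

    def at(self, t: float) -> float:
        """F1 at the grid threshold closest to ``t``."""
        i = int(np.argmin(np.abs(self.thresholds - t)))
        return float(self.f1[i])


def default_thresholds(step: float = 0.05) -> np.ndarray:
    """The standard evaluation grid: 0.05 to 0.90 inclusive."""
    n = int(round((0.90 - 0.05) / step)) + 1
    return np.round(np.linspace(0.05, 0.90, n), 10)


def iou(gt_pixels: np.ndarray, est_pixels: np.ndarray) -> float:
    """Intersection over union of two boolean pixel masks."""
    gt_pixels = np.asarray(gt_pixels, dtype=bool)
    est_pixels = np.asarray(est_pixels, dtype=bool)
    union = np.count_nonzero(gt_pixels | est_pixels)
    if union == 0:
        raise ValueError("both pixel sets are empty")
    inter = np.count_nonzero(gt_pixels & est_pixels)
    return inter / union


def _intersection_table(gt: np.ndarray, est: np.ndarray):
    """Areas per id and intersection counts for co-occurring (gt, est) pairs."""
    gt_areas = np.bincount(gt.ravel())
    est_areas = np.bincount(est.ravel())
    both = (gt > 0) & (est > 0)
    inter: dict[tuple[int, int], int] = {}
    if both.any():
        pair_codes = gt[both].astype(np.int64) * (est.max() + 1) + est[both]
        codes, counts = np.unique(pair_codes, return_counts=True)
        for code, cnt in zip(codes, counts):
            g, e = divmod(int(code), int(est.max() + 1))
            inter[(g, e)] = int(cnt)
    return gt_areas, est_areas, inter


def mutual_best_matching(gt: np.ndarray, est: np.ndarray) -> Matching:
    """Pair nuclei that are mutually each other's strict-best IoU partner.

    Comparisons between IoUs ``i1/u1`` and ``i2/u2`` are made as
    ``i1*u2 <?> i2*u1`` on integers, so exact ties (which yield no match)
    are detected without floating-point ambiguity.
    """
    gt = _as_instance_array(gt)
    est = _as_instance_array(est)
    if gt.shape != est.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {est.shape}")
    gt_areas, est_areas, inter = _intersection_table(gt, est)
    n_gt = int(np.count_nonzero(gt_areas[1:]))
    n_est = int(np.count_nonzero(est_areas[1:]))

    # group positive-intersection entries by row (gt id) and column (est id)
    by_gt: dict[int, list[tuple[int, int, int]]] = {}
    by_est: dict[int, list[tuple[int, int, int]]] = {}
    for (g, e), i_ge in inter.items():
        u_ge = int(gt_areas[g]) + int(est_areas[e]) - i_ge
        by_gt.setdefault(g, []).append((e, i_ge, u_ge))
        by_est.setdefault(e, []).append((g, i_ge, u_ge))

    pairs = []
    for g, row in by_gt.items():
        for e, i_ge, u_ge in row:
            # strict max over the gt row
            if any(
                e2 != e and i_ge * u2 <= i2 * u_ge for e2, i2, u2 in row
            ):
                continue
            # strict max over the est column
            col = by_est[e]
            if any(
                g2 != g and i_ge * u2 <= i2 * u_ge for g2, i2, u2 in col
            ):
                continue
            pairs.append((g, e, i_ge / u_ge))
    pairs.sort()
    return Matching(pairs=tuple(pairs), n_gt=n_gt, n_est=n_est)


def f1_curve(
    gt: np.ndarray,
    est: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> EvalCurve:
    """Evaluate F1 over a threshold grid via the mutual-best matching.

    A pair counts as a true positive at threshold t iff its IoU* is
    strictly greater than t. When both maps are empty the F1 is defined
    as 1 at every threshold (perfect agreement on nothing); when exactly
    one side is empty the F1 is 0.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    t = np.asarray(thresholds, dtype=np.float64)
    if t.size and (t.min() <= 0.0 or t.max() >= 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    m = mutual_best_matching(gt, est)
    ious = m.iou_values
    tp = np.array([int(np.count_nonzero(ious > ti)) for ti in t], dtype=np.int64)
    fn = m.n_gt - tp
    fp = m.n_est - tp
    denom = 2 * tp + fn + fp
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 1.0)
    return EvalCurve(thresholds=t, tp=tp, fn=fn, fp=fp, f1=f1,
                     n_gt=m.n_gt, n_est=m.n_est)


def aggregate_curves(curves: Iterable[EvalCurve]):
    """Per-threshold mean and population standard deviation of F1.

    Returns (thresholds, mean_f1, std_f1). All curves must share one
    threshold grid.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to aggregate")
    t0 = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != t0.shape or not np.allclose(c.thresholds, t0):
            raise ValueError("curves have mismatched threshold grids")
    stack = np.vstack([c.f1 for c in curves])
    return t0.copy(), stack.mean(axis=0), stack.std(axis=0, ddof=0)
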