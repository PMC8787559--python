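"""Semantic-to-instance post-processing.

Converts the three-channel class-probability output of a semantic
segmentation network (inner nucleus / contour / background, softmax
normalized) into an instance label map:

1. *Seeds* — 8-connected components of ``p_inner - p_contour > 0.35``.
   Subtracting the contour channel carves gaps between touching nuclei,
   so each nucleus contributes its own seed component.
2. *Voronoi assignment* — every pixel takes the id of its nearest seed
   component (Euclidean distance to the component's pixel set).
3. *Object mask* — pixels with ``p_background < 0.95`` are object; the
   tessellation is multiplied by this mask.
4. *Gap repair* — the thin unassigned strip the tessellation leaves
   between nuclei is filled by assigning each unlabeled object pixel the
   modal adjacent nucleus id (dilation-by-one, iterated).
5. Nuclei smaller than 35 pixels are removed and ids renormalized.

Thresholds are strict: seeds require ``p_inner - p_contour`` strictly
above the seed threshold, the object mask requires ``p_background``
strictly below the background threshold ("inferior to").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .labelcodec import SQUARE3, normalize_ids

_EPS_SUM = 1e-3


@dataclass(frozen=True)
class ProbabilityMaps:
    """Per-pixel class probabilities (inner, contour, background).

    All three channels share one shape; values lie in [0, 1] and the
    per-pixel channel sum is 1 within 1e-3 (softmax contract). Violations
    raise ``ValueError`` at construction.
    """

    p_inner: np.ndarray
    p_contour: np.ndarray
    p_background: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.p_inner, dtype=np.float64)
        pc = np.asarray(self.p_contour, dtype=np.float64)
        pb = np.asarray(self.p_background, dtype=np.float64)
        if pi.ndim != 2 or pi.shape != pc.shape or pi.shape != pb.shape:
            raise ValueError("probability channels must be 2D and share one shape")
        if pi.size == 0:
            raise ValueError("probability maps must be at least 1x1")
        for name, ch in (("inner", pi), ("contour", pc), ("background", pb)):
            if ch.min() < 0.0 or ch.max() > 1.0:
                raise ValueError(f"{name} channel has values outside [0, 1]")
        total = pi + pc + pb
        dev = np.abs(total - 1.0)
        worst = np.unravel_index(np.argmax(dev), dev.shape)
        if dev[worst] > _EPS_SUM:
            raise ValueError(
                f"channel sum {total[worst]:.6f} at pixel {tuple(int(i) for i in worst)} "
                f"violates softmax contract (|sum - 1| <= {_EPS_SUM})"
            )
        object.__setattr__(self, "p_inner", pi)
        object.__setattr__(self, "p_contour", pc)
        object.__setattr__(self, "p_background", pb)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_inner.shape

    @classmethod
    def from_stack(cls, stack: np.ndarray) -> "ProbabilityMaps":
        """Build from a (3, H, W) stack in channel order inner, contour, background."""
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(f"expected a (3, H, W) stack, got shape {stack.shape}")
        return cls(stack[0], stack[1], stack[2])

    def to_stack(self) -> np.ndarray:
        return np.stack([self.p_inner, self.p_contour, self.p_background])


@dataclass(frozen=True)
class PostprocessParams:
    """Parameters of the semantic-to-instance pipeline (defaults per the macro)."""

    seed_threshold: float = 0.35
    background_threshold: float = 0.95
    min_area: int = 35
    gap_dilation_radius: int = 1

    def __post_init__(self):
        if not (0.0 < self.seed_threshold < 1.0):
            raise ValueError("seed_threshold must be in (0, 1)")
        if not (0.0 < self.background_threshold < 1.0):
            raise ValueError("background_threshold must be in (0, 1)")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.gap_dilation_radius < 0:
            raise ValueError("gap_dilation_radius must be >= 0")


def seeds_from_probabilities(
    probs: ProbabilityMaps, seed_threshold: float = 0.35
) -> np.ndarray:
    """Label the 8-connected components of ``p_inner - p_contour > threshold``."""
    diff = probs.p_inner - probs.p_contour
    return cc_label(diff > seed_threshold, background=0, connectivity=2).astype(np.int64)


def voronoi_assign(seeds: np.ndarray) -> np.ndarray:
    """Assign every pixel the id of its nearest seed component.

    Distance is the Euclidean distance from the pixel to the component's
    pixel set; seed pixels keep their own id. Pixels exactly equidistant
    between two components are assigned the smaller component id, making
    the tessellation deterministic.
    """
    seeds = np.asarray(seeds)
    if seeds.ndim != 2:
        raise ValueError("seed map must be 2D")
    ids = np.unique(seeds)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no seeds")
    out = np.full(seeds.shape, 0, dtype=np.int64)
    best = np.full(seeds.shape, np.inf)
    # One exact EDT per component; strict improvement keeps the smallest id
    # on exact ties. Squared distances are integers, so float comparisons
    # here are exact.
    for i in ids:
        d = ndi.distance_transform_edt(seeds != i)
        closer = d * d < best
        out[closer] = i
        best[closer] = (d * d)[closer]
    return out


def object_mask(probs: ProbabilityMaps, background_threshold: float = 0.95) -> np.ndarray:
    """Boolean object mask: true exactly where ``p_background < threshold``."""
    return probs.p_background < background_threshold


def _fill_gaps(labels: np.ndarray, mask: np.ndarray, radius: int) -> np.ndarray:
    """Assign unlabeled object pixels the modal 8-adjacent id, iterated.

    Ties on the modal count go to the smaller id. Up to ``radius``
    dilation passes are applied; pixels still unreachable stay 0.
    """
    labels = labels.copy()
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for _ in range(radius):
        holes = (labels == 0) & mask
        if not holes.any():
            break
        rows, cols = np.nonzero(holes)
        h, w = labels.shape
        neigh = np.zeros((len(shifts), rows.size), dtype=np.int64)
        for k, (dr, dc) in enumerate(shifts):
            rr = rows + dr
            cc = cols + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            neigh[k, ok] = labels[rr[ok], cc[ok]]
        new_vals = np.zeros(rows.size, dtype=np.int64)
        for j in range(rows.size):
            vals = neigh[:, j]
            vals = vals[vals > 0]
            if vals.size == 0:
                continue
            counts = np.bincount(vals)
            new_vals[j] = int(np.argmax(counts))  # argmax -> smallest id on ties
        changed = new_vals > 0
        labels[rows[changed], cols[changed]] = new_vals[changed]
        if not changed.any():
            break
    return labels


def instances_from_probabilities(
    probs: ProbabilityMaps, params: PostprocessParams | None = None
) -> np.ndarray:
    """Full semantic-to-instance pipeline; returns a normalized instance map.

    Returns an all-zero map when no seed survives thresholding or when no
    nucleus reaches ``min_area``.
    """
    if params is None:
        params = PostprocessParams()
    seeds = seeds_from_probabilities(probs, params.seed_threshold)
    if seeds.max() == 0:
        return np.zeros(probs.shape, dtype=np.int64)
    tess = voronoi_assign(seeds)
    mask = object_mask(probs, params.background_threshold)
    labels = np.where(mask, tess, 0)
    # The object mask can fragment a Voronoi cell; only the fragment
    # containing the seed is the nucleus (stray fragments are noise
    # speckles far from any seed). Keeps each id a single component and
    # the nucleus count bounded by the seed count.
    for i in np.unique(labels[labels > 0]):
        cell = labels == i
        frags = cc_label(cell, background=0, connectivity=2)
        seeded = np.unique(frags[cell & (seeds == i)])
        keep = np.isin(frags, seeded[seeded > 0])
        labels[cell & ~keep] = 0
    labels = _fill_gaps(labels, mask, params.gap_dilation_radius)
    if params.min_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_area)
        kill = np.isin(labels, small[small > 0])
        labels[kill] = 0
    return normalize_ids(labels)
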