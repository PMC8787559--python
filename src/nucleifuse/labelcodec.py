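"""Three-class semantic encoding of nucleus instance label maps.

An *instance map* is a 2D non-negative integer array: 0 is background and
each positive id labels one 8-connected nucleus. Semantic networks for
nucleus separation are trained on a three-class per-pixel encoding of such
maps — background, inner nucleus and nucleus contour — with the contour
class dilated between touching nuclei so that the network learns to keep
adjacent nuclei apart. This module provides that encoding, the
inverse-frequency class weights used to balance the cross-entropy loss,
and the id-normalization helper the rest of the package relies on.

Class integer coding, fixed across the whole package and all files written
by it: background = 0, inner = 1, contour = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

BACKGROUND = 0
INNER = 1
CONTOUR = 2

CLASS_NAMES = ("background", "inner", "contour")

#: 8-connectivity structuring element, used everywhere in the package.
SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights for a weighted cross-entropy loss.

    ``w_c = T / (C * n_c)`` with ``T`` the pooled pixel count, ``C = 3``
    classes and ``n_c`` the pooled count of class ``c``; equal-frequency
    classes give weights (1, 1, 1).
    """

    w_background: float
    w_inner: float
    w_contour: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_background, self.w_inner, self.w_contour)


def _as_instance_array(instances: np.ndarray) -> np.ndarray:
    arr = np.asarray(instances)
    if arr.ndim != 2:
        raise ValueError(f"instance map must be 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError("instance map must be integer-valued")
    if arr.size and arr.min() < 0:
        raise ValueError("instance map must be non-negative")
    return arr.astype(np.int64, copy=False)


def normalize_ids(instances: np.ndarray) -> np.ndarray:
    """Relabel an instance map to consecutive ids 1..K.

    Any id occupying several 8-connected components is split into one id
    per component. Output ids are assigned in order of first raster-scan
    (row-major) appearance, making the operation idempotent and
    deterministic.
    """
    arr = _as_instance_array(instances)
    if arr.size == 0 or arr.max() == 0:
        return np.zeros_like(arr, dtype=np.int64)
    # skimage's label() on an integer array separates touching regions of
    # *different* value, splitting multi-component ids along the way.
    comp = cc_label(arr, background=0, connectivity=2).astype(np.int64)
    flat = comp.ravel()
    nonzero = np.flatnonzero(flat)
    # order of first appearance in raster scan
    _, first_idx = np.unique(flat[nonzero], return_index=True)
    order = np.argsort(nonzero[first_idx])
    old_ids = np.unique(flat[nonzero])[order]
    lut = np.zeros(comp.max() + 1, dtype=np.int64)
    lut[old_ids] = np.arange(1, old_ids.size + 1)
    return lut[comp]


def encode_three_class(
    instances: np.ndarray,
    contour_width: int = 1,
    touching_dilation_radius: int = 1,
) -> np.ndarray:
    """Encode an instance map into {background, inner, contour} classes.

    The contour band of a nucleus consists of its pixels within
    ``contour_width`` (Chebyshev distance, matching 8-connectivity) of a
    pixel carrying a different label or background. Contour pixels shared
    between two distinct nuclei are additionally dilated by
    ``touching_dilation_radius`` to widen the separating band; the dilated
    band overwrites inner pixels but stays within the foreground so that
    background pixels are never reclassified.

    Parameters
    ----------
    instances : 2D int array
        Instance label map (0 = background).
    contour_width : int
        Width of the per-nucleus boundary band, >= 1.
    touching_dilation_radius : int
        Extra dilation of contours between touching nuclei, >= 0.

    Returns
    -------
    2D uint8 array with values in {0, 1, 2}.
    """
    if contour_width < 1:
        raise ValueError("contour_width must be >= 1")
    if touching_dilation_radius < 0:
        raise ValueError("touching_dilation_radius must be >= 0")
    arr = _as_instance_array(instances)
    out = np.zeros(arr.shape, dtype=np.uint8)
    if arr.size == 0 or arr.max() == 0:
        return out

    fg = arr > 0
    # A pixel is inner iff every pixel within Chebyshev radius
    # `contour_width` carries the same label: grey erosion == grey dilation
    # == own label over the (2w+1)^2 window.
    size = 2 * contour_width + 1
    lo = ndi.minimum_filter(arr, size=size, mode="constant", cval=0)
    hi = ndi.maximum_filter(arr, size=size, mode="constant", cval=0)
    inner = fg & (lo == arr) & (hi == arr)
    out[fg] = CONTOUR
    out[inner] = INNER

    # Touching band: foreground pixels 8-adjacent to a different positive id.
    # Detected on the positive labels only (background excluded via min
    # filter over a masked copy).
    big = np.int64(np.iinfo(np.int32).max)
    masked_lo = np.where(fg, arr, big)
    lo_pos = ndi.minimum_filter(masked_lo, size=3, mode="constant", cval=big)
    hi_pos = ndi.maximum_filter(arr, size=3, mode="constant", cval=0)
    touching = fg & (lo_pos < arr) | fg & (hi_pos > arr)
    if touching.any() and touching_dilation_radius > 0:
        touching = ndi.binary_dilation(
            touching, structure=SQUARE3, iterations=touching_dilation_radius
        )
    out[touching & fg] = CONTOUR
    return out


def compute_class_weights(class_maps: Iterable[np.ndarray]) -> ClassWeights:
    """Pool pixels over class maps and return inverse-proportion weights.

    Raises ``ValueError`` if no maps are given or a class is absent from
    the pooled pixels (its inverse proportion would be infinite).
    """
    counts = np.zeros(3, dtype=np.int64)
    n_maps = 0
    for cm in class_maps:
        cm = np.asarray(cm)
        if cm.ndim != 2:
            raise ValueError("class maps must be 2D")
        if cm.size and (cm.min() < 0 or cm.max() > 2):
            raise ValueError("class map values must be in {0, 1, 2}")
        counts += np.bincount(cm.ravel().astype(np.int64), minlength=3)[:3]
        n_maps += 1
    if n_maps == 0:
        raise ValueError("at least one class map is required")
    for c, n in enumerate(counts):
        if n == 0:
            raise ValueError(
                f"class '{CLASS_NAMES[c]}' has zero pixels in the pooled maps; "
                "cannot form inverse-proportion weight"
            )
    total = counts.sum()
    w = total / (3.0 * counts)
    return ClassWeights(w_background=float(w[0]), w_inner=float(w[1]), w_contour=float(w[2]))


def instance_areas(instances: np.ndarray) -> dict[int, int]:
    """Pixel area of each positive id in the map."""
    arr = _as_instance_array(instances)
    if arr.size == 0:
        return {}
    counts = np.bincount(arr.ravel())
    return {int(i): int(c) for i, c in enumerate(counts) if i > 0 and c > 0}
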