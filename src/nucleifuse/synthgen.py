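"""Synthetic stand-ins for trained-network outputs.

The segmentation networks themselves (semantic, instance, generative)
are out of scope here; this module produces the three artifacts they
would supply so the post-processing, fusion and evaluation stages can be
exercised end-to-end on purely synthetic data:

* ``render_image`` — a pseudo-fluorescence intensity image from a mask
  (bright textured nuclei over dim background, blur, additive noise);
* ``probabilities_from_instances`` — plausible softmax probability maps
  from a ground-truth mask (smoothed, perturbed one-hot encoding of the
  three-class map);
* ``corrupt_instances`` — a degraded "prediction" with controlled error
  modes (dropped, merged, split nuclei, jittered boundaries).

The noise models are declared test instruments: they make no claim
about the error statistics of any particular trained network. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .instantiate import ProbabilityMaps
from .labelcodec import (
    CONTOUR,
    INNER,
    SQUARE3,
    _as_instance_array,
    encode_three_class,
    instance_areas,
    normalize_ids,
)


@dataclass(frozen=True)
class RenderParams:
    """Pseudo-fluorescence rendering parameters (arbitrary intensity units)."""

    fg_mean: float = 0.8
    bg_mean: float = 0.1
    blur_sigma: float = 1.0
    noise_sd: float = 0.05
    texture_amplitude: float = 0.1

    def __post_init__(self):
        if not (self.fg_mean > self.bg_mean >= 0):
            raise ValueError("need fg_mean > bg_mean >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class CorruptionParams:
    """Error-mode probabilities for simulated instance predictions."""

    p_drop: float = 0.0
    p_merge: float = 0.0
    p_split: float = 0.0
    boundary_jitter: int = 0

    def __post_init__(self):
        for name in ("p_drop", "p_merge", "p_split"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


def render_image(
    mask: np.ndarray, params: RenderParams | None = None, rng_seed: int = 0
) -> np.ndarray:
    """Render a mask as a pseudo-fluorescence intensity image."""
    if params is None:
        params = RenderParams()
    arr = _as_instance_array(mask)
    rng = np.random.default_rng(rng_seed)
    img = np.full(arr.shape, params.bg_mean, dtype=np.float64)
    fg = arr > 0
    if params.texture_amplitude > 0:
        # low-frequency chromatin-like texture inside nuclei
        field = ndi.gaussian_filter(rng.normal(0, 1, arr.shape), sigma=2.0)
        peak = np.abs(field).max()
        if peak > 0:
            field = field / peak * params.texture_amplitude
        img[fg] = params.fg_mean + field[fg]
    else:
        img[fg] = params.fg_mean
    if params.blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, arr.shape)
    return img


def probabilities_from_instances(
    mask: np.ndarray,
    contour_width: int = 1,
    touching_dilation_radius: int = 1,
    softness: float = 0.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> ProbabilityMaps:
    """Simulate semantic-network softmax output for a ground-truth mask.

    The three-class encoding of the mask is one-hot encoded, each channel
    Gaussian-smoothed with sigma = ``softness``, perturbed by clipped
    Gaussian noise, and renormalized per pixel to sum to 1. With
    ``softness = noise_sd = 0`` the result is the exact one-hot encoding.
    """
    classes = encode_three_class(mask, contour_width, touching_dilation_radius)
    rng = np.random.default_rng(rng_seed)
    channels = []
    for c in (INNER, CONTOUR, 0):
        ch = (classes == c).astype(np.float64)
        if softness > 0:
            ch = ndi.gaussian_filter(ch, sigma=softness)
        if noise_sd > 0:
            ch = np.clip(ch + rng.normal(0, noise_sd, ch.shape), 0.0, None)
        channels.append(ch)
    stack = np.stack(channels)
    total = stack.sum(axis=0)
    dead = total == 0  # all channels zeroed by noise clipping: call it background
    stack[2][dead] = 1.0
    total[dead] = 1.0
    stack = stack / total
    return ProbabilityMaps.from_stack(np.clip(stack, 0.0, 1.0))


def _adjacent_pairs(arr: np.ndarray) -> list[tuple[int, int]]:
    """Pairs of distinct positive ids that are 8-adjacent somewhere."""
    pairs: set[tuple[int, int]] = set()
    h, w = arr.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        ra = slice(0, h - dr)
        rb = slice(dr, h)
        ca = slice(0, w - dc) if dc >= 0 else slice(-dc, w)
        cb = slice(dc, w) if dc >= 0 else slice(0, w + dc)
        a = arr[ra, ca]
        b = arr[rb, cb]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            for x, y in zip(a[sel], b[sel]):
                pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    return sorted(pairs)


def _split_nucleus(arr: np.ndarray, nid: int, next_id: int, rng: np.random.Generator) -> int:
    """Split a nucleus along a random chord through its centroid."""
    rows, cols = np.nonzero(arr == nid)
    if rows.size < 2:
        return next_id
    r0, c0 = rows.mean(), cols.mean()
    theta = rng.uniform(0, np.pi)
    side = (rows - r0) * np.cos(theta) + (cols - c0) * np.sin(theta) > 0
    if side.all() or not side.any():
        return next_id
    arr[rows[side], cols[side]] = next_id
    return next_id + 1


def _jitter_nucleus(arr: np.ndarray, nid: int, amount: int, grow: bool) -> None:
    mask = arr == nid
    if grow:
        grown = ndi.binary_dilation(mask, structure=SQUARE3, iterations=amount)
        arr[grown & (arr == 0)] = nid  # dilation only claims background
    else:
        shrunk = ndi.binary_erosion(mask, structure=SQUARE3, iterations=amount)
        if shrunk.any():  # never let a nucleus vanish from jitter alone
            arr[mask & ~shrunk] = 0


def corrupt_instances(
    mask: np.ndarray, params: CorruptionParams | None = None, rng_seed: int = 0
) -> np.ndarray:
    """Degrade a ground-truth instance map into a simulated prediction.

    Each nucleus is dropped with probability ``p_drop``; each 8-adjacent
    pair of surviving nuclei is merged with probability ``p_merge``; each
    nucleus is split along a random chord with probability ``p_split``;
    finally every nucleus boundary is jittered by dilating or eroding
    (coin flip) up to ``boundary_jitter`` pixels, dilation claiming only
    background. Identity when all probabilities and the jitter are 0.
    """
    if params is None:
        params = CorruptionParams()
    arr = normalize_ids(mask)
    rng = np.random.default_rng(rng_seed)
    ids = sorted(instance_areas(arr))

    if params.p_drop > 0:
        for nid in ids:
            if rng.random() < params.p_drop:
                arr[arr == nid] = 0
        ids = sorted(instance_areas(arr))

    if params.p_merge > 0:
        merged: set[int] = set()
        for a, b in _adjacent_pairs(arr):
            if a in merged or b in merged:
                continue
            if rng.random() < params.p_merge:
                arr[arr == b] = a
                merged.update((a, b))
        ids = sorted(instance_areas(arr))

    if params.p_split > 0:
        next_id = (int(arr.max()) + 1) if ids else 1
        for nid in ids:
            if rng.random() < params.p_split:
                next_id = _split_nucleus(arr, nid, next_id, rng)
        ids = sorted(instance_areas(arr))

    if params.boundary_jitter > 0:
        for nid in ids:
            amount = int(rng.integers(1, params.boundary_jitter + 1))
            grow = bool(rng.random() < 0.5)
            _jitter_nucleus(arr, nid, amount, grow)

    return normalize_ids(arr)
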