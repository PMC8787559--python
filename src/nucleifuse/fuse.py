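"""Fusion of an instance segmentation with a semantic-derived segmentation.

The combined result starts from the instance-network nuclei. Nuclei whose
overlap with the semantic foreground is below 20% of their own area are
discarded as hallucinations; semantic-derived nuclei whose overlap with
the instance foreground is below 33% of their own area are added as new
nuclei (clipped to pixels not already occupied); finally nuclei smaller
than 35 pixels are dropped.

Both overlap fractions are measured against the *other map's full
foreground*, relative to the area of the nucleus being tested. Rule
boundaries follow the wording "inferior to": discarded iff overlap
strictly < 0.20 (kept at exactly 20%), added iff overlap strictly < 0.33.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labelcodec import _as_instance_array, normalize_ids


@dataclass(frozen=True)
class FusionParams:
    keep_overlap_min: float = 0.20
    add_overlap_max: float = 0.33
    min_area: int = 35

    def __post_init__(self):
        for name in ("keep_overlap_min", "add_overlap_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


def overlap_fraction(nucleus_mask: np.ndarray, other: np.ndarray) -> float:
    """Fraction of a nucleus's pixels covered by the other map's foreground."""
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    other = _as_instance_array(other)
    area = int(nucleus_mask.sum())
    if area == 0:
        raise ValueError("nucleus pixel set is empty")
    return float(np.count_nonzero(other[nucleus_mask] > 0)) / area


def _per_id_overlap(labels: np.ndarray, other_fg: np.ndarray) -> dict[int, float]:
    """Overlap fraction with `other_fg` for every positive id, in one pass."""
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    hits = np.bincount(labels[other_fg & (labels > 0)], minlength=labels.max() + 1)
    return {int(i): float(hits[i]) / float(a) for i, a in zip(ids, areas)}


def fuse_instances(
    instance_seg: np.ndarray,
    semantic_seg: np.ndarray,
    params: FusionParams | None = None,
) -> np.ndarray:
    """Combine two instance maps with the keep / add / area-filter rules.

    Kept instance-segmentation nuclei take precedence: added
    semantic-derived nuclei are clipped to pixels they do not occupy, and
    a clipped addition falling below ``min_area`` is dropped like any
    other small nucleus. Output ids are renormalized.
    """
    if params is None:
        params = FusionParams()
    a = _as_instance_array(instance_seg)
    b = _as_instance_array(semantic_seg)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")

    out = np.zeros(a.shape, dtype=np.int64)
    next_id = 1

    keep_frac = _per_id_overlap(a, b > 0)
    for i, frac in keep_frac.items():
        if frac >= params.keep_overlap_min:  # "inferior to 20%" discarded
            out[a == i] = next_id
            next_id += 1

    kept_fg = out > 0
    add_frac = _per_id_overlap(b, a > 0)
    for i, frac in add_frac.items():
        if frac < params.add_overlap_max:  # "inferior to 33%" added
            pix = (b == i) & ~kept_fg
            if pix.any():
                out[pix] = next_id
                next_id += 1

    if params.min_area > 0:
        counts = np.bincount(out.ravel())
        small = np.flatnonzero(counts < params.min_area)
        out[np.isin(out, small[small > 0])] = 0
    return normalize_ids(out)
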