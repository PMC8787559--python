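"""Parametric simulation of nuclei mask images.

Dense fields of epithelial nuclei are emulated as random ellipses: the
number of nuclei per image follows a Gaussian (truncated at zero,
rounded), nucleus areas follow a Gumbel distribution (capturing the
heavy right tail of real nucleus-size histograms), orientations are
uniform, and eccentricity is drawn so that the semi-major axis has a 20%
coefficient of variation around the circular value sqrt(s/pi) while the
rasterized area stays exactly s = pi*a*b.

Both distributions can be fitted from annotated instance maps, closing
the loop: fit on real (or previously simulated) data, then generate
arbitrarily many mask images with the same count/size statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .labelcodec import SQUARE3, _as_instance_array, instance_areas

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class CountModel:
    """Gaussian model of nuclei count per image (truncated at 0, rounded)."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class SizeModel:
    """Gumbel model of nucleus area in pixels^2.

    ``location`` is the Gumbel mode mu, ``scale`` the spread beta > 0.
    Samples are truncated below at ``min_area`` (implausibly small nuclei
    are redrawn).
    """

    location: float
    scale: float
    min_area: float = 35.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: center, area, orientation, axis ratio.

    Semi-axes are a = sqrt(s*r/pi) and b = sqrt(s/(pi*r)), so that
    pi*a*b = s exactly whatever the ratio r = a/b.
    """

    center: tuple[float, float]
    area: float
    orientation: float
    axis_ratio: float

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.axis_ratio <= 0:
            raise ValueError("axis_ratio must be > 0")

    @property
    def semi_axes(self) -> tuple[float, float]:
        a = math.sqrt(self.area * self.axis_ratio / math.pi)
        b = math.sqrt(self.area / (math.pi * self.axis_ratio))
        return a, b


def fit_count_model(instance_maps: Iterable[np.ndarray]) -> CountModel:
    """Sample mean and sample standard deviation of nucleus counts per map."""
    counts = [len(instance_areas(m)) for m in instance_maps]
    if len(counts) < 2:
        raise ValueError("at least 2 instance maps are required to fit counts")
    arr = np.asarray(counts, dtype=np.float64)
    return CountModel(mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def fit_size_model(
    instance_maps: Iterable[np.ndarray],
    min_area: float = 35.0,
    method: str = "moments",
) -> SizeModel:
    """Fit a Gumbel distribution to the pooled nucleus areas.

    Method of moments (default, closed-form): beta = sd*sqrt(6)/pi and
    mu = mean - gamma*beta with gamma the Euler-Mascheroni constant and
    sd the sample standard deviation. ``method='mle'`` uses maximum
    likelihood instead.
    """
    areas: list[float] = []
    for m in instance_maps:
        areas.extend(instance_areas(m).values())
    if len(areas) < 10:
        raise ValueError("at least 10 pooled nuclei are required to fit sizes")
    arr = np.asarray(areas, dtype=np.float64)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate size sample: all areas identical (sd = 0)")
    if method == "moments":
        beta = sd * math.sqrt(6.0) / math.pi
        mu = float(arr.mean()) - EULER_GAMMA * beta
    elif method == "mle":
        mu, beta = stats.gumbel_r.fit(arr)
    else:
        raise ValueError(f"unknown fitting method {method!r}")
    return SizeModel(location=float(mu), scale=float(beta), min_area=min_area)


def rasterize_ellipse(spec: EllipseSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixel centers inside the ellipse (clipped to shape)."""
    h, w = shape
    a, b = spec.semi_axes
    r0, c0 = spec.center
    rad = max(a, b)
    rmin = max(0, int(math.floor(r0 - rad)))
    rmax = min(h - 1, int(math.ceil(r0 + rad)))
    cmin = max(0, int(math.floor(c0 - rad)))
    cmax = min(w - 1, int(math.ceil(c0 + rad)))
    mask = np.zeros(shape, dtype=bool)
    if rmin > rmax or cmin > cmax:
        return mask
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr = rr - r0
    dc = cc - c0
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[rmin : rmax + 1, cmin : cmax + 1] = inside
    return mask


def _draw_truncated_gumbel(size_model: SizeModel, rng: np.random.Generator) -> float:
    for _ in range(1000):
        s = float(rng.gumbel(size_model.location, size_model.scale))
        if s >= size_model.min_area:
            return s
    # pathological parameters: fall back to the truncation point
    return float(size_model.min_area)


def sample_ellipse(
    size_model: SizeModel,
    shape: tuple[int, int],
    rng: np.random.Generator,
    ratio_sd_factor: float = 0.2,
    keep_inside: bool = False,
) -> EllipseSpec:
    """Draw one ellipse: Gumbel area, uniform orientation and center.

    The semi-major axis is drawn as a ~ N(sqrt(s/pi), ratio_sd_factor *
    sqrt(s/pi)) truncated positive; the companion axis b = s/(pi*a)
    preserves the drawn area exactly. Centers are uniform over the image;
    with ``keep_inside`` the center range is shrunk by the ellipse's
    bounding radius so no nucleus is clipped at the border.
    """
    h, w = shape
    s = _draw_truncated_gumbel(size_model, rng)
    theta = float(rng.uniform(0.0, math.pi))
    a_mean = math.sqrt(s / math.pi)
    a = -1.0
    while a <= 0.0:
        a = float(rng.normal(a_mean, ratio_sd_factor * a_mean))
    ratio = math.pi * a * a / s  # r = a/b given pi*a*b = s
    if keep_inside:
        rad = max(a, s / (math.pi * a)) + 1.0
        lo_r, hi_r = min(rad, h / 2), max(h - rad, h / 2)
        lo_c, hi_c = min(rad, w / 2), max(w - rad, w / 2)
        center = (float(rng.uniform(lo_r, hi_r)), float(rng.uniform(lo_c, hi_c)))
    else:
        center = (float(rng.uniform(0, h)), float(rng.uniform(0, w)))
    return EllipseSpec(center=center, area=s, orientation=theta, axis_ratio=ratio)


def sample_mask_image(
    count_model: CountModel,
    size_model: SizeModel,
    shape: tuple[int, int] = (256, 256),
    ratio_sd_factor: float = 0.2,
    max_overlap: float = 0.0,
    min_gap: int = 0,
    keep_inside: bool = False,
    max_retries: int = 50,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one instance map of random ellipse nuclei.

    The nucleus count is a truncated-rounded Gaussian draw; each nucleus
    is an ellipse placed at a uniform random center. A placement whose
    overlap fraction with already-placed nuclei exceeds ``max_overlap``
    is redrawn up to ``max_retries`` times, then skipped. ``min_gap`` > 0
    additionally requires the candidate, dilated by that many pixels, to
    be free of other nuclei, producing strictly separated masks;
    ``keep_inside`` prevents border clipping. Deterministic for a fixed
    integer seed.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("image sides must be >= 16 pixels")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = max(0, int(round(rng.normal(count_model.mean, count_model.sd))))
    out = np.zeros(shape, dtype=np.int64)
    next_id = 1
    for _ in range(n):
        for _attempt in range(max_retries + 1):
            spec = sample_ellipse(size_model, shape, rng, ratio_sd_factor, keep_inside)
            mask = rasterize_ellipse(spec, shape)
            area = int(mask.sum())
            if area == 0:
                continue
            footprint = mask
            if min_gap > 0:
                footprint = ndi.binary_dilation(mask, structure=SQUARE3, iterations=min_gap)
            overlap = np.count_nonzero(out[footprint] > 0) / area
            if overlap <= max_overlap:
                out[mask & (out == 0)] = next_id
                next_id += 1
                break
    from .labelcodec import normalize_ids

    return normalize_ids(out)


def generate_dataset(
    n_images: int,
    count_model: CountModel,
    size_model: SizeModel,
    shape: tuple[int, int] = (256, 256),
    ratio_sd_factor: float = 0.2,
    max_overlap: float = 0.0,
    min_gap: int = 0,
    keep_inside: bool = False,
    max_retries: int = 50,
    rng_seed: int = 0,
) -> list[np.ndarray]:
    """Simulate ``n_images`` independent mask images, seeds = seed + index."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return [
        sample_mask_image(
            count_model,
            size_model,
            shape=shape,
            ratio_sd_factor=ratio_sd_factor,
            max_overlap=max_overlap,
            min_gap=min_gap,
            keep_inside=keep_inside,
            max_retries=max_retries,
            rng_seed=rng_seed + i,
        )
        for i in range(n_images)
    ]
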