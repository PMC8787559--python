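"""File I/O and plain-text configuration.

Label maps travel as single-channel 16-bit unsigned TIFF or PNG (more
than 65535 nuclei per image is unsupported, far above realistic tissue
densities); class maps as 8-bit single-channel images; probability maps
as one 3-page floating-point TIFF (page order inner, contour,
background) or three separate single-channel TIFFs. Image origin is the
top-left corner, arrays are row-major and 0-based throughout.

Pipeline configuration is a flat plain-text ``key=value`` file with
'.'-decimal floats, no locale dependence; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .evaluate import EvalCurve, default_thresholds
from .fuse import FusionParams
from .instantiate import PostprocessParams, ProbabilityMaps
from .labelcodec import _as_instance_array, normalize_ids

MAX_ID = 65535


def write_instance_map(instances: np.ndarray, path: str | Path) -> None:
    """Write an instance map as 16-bit unsigned TIFF or PNG."""
    arr = _as_instance_array(instances)
    if arr.size and arr.max() > MAX_ID:
        raise ValueError(f"id overflow: max id {arr.max()} exceeds {MAX_ID} (16-bit)")
    path = Path(path)
    data = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_instance_map(path: str | Path, normalize: bool = False) -> np.ndarray:
    """Read an instance map; validates single-channel integer pixels.

    Float-valued images whose values are all integral are accepted and
    cast. ``normalize=True`` additionally relabels ids to 1..K with
    8-connected-component splitting.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: expected a single-channel label image, got {arr.shape[-1] if arr.shape[-1] <= 4 else arr.shape[0]} channels"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.floor(arr)):
            raise ValueError(f"{path}: non-integer pixel values in a label image")
        arr = arr.astype(np.int64)
    arr = _as_instance_array(arr)
    if arr.size and arr.max() > MAX_ID:
        raise ValueError(f"{path}: id overflow beyond {MAX_ID}")
    return normalize_ids(arr) if normalize else arr


def write_class_map(classes: np.ndarray, path: str | Path) -> None:
    """Write a three-class map as an 8-bit single-channel image."""
    arr = np.asarray(classes)
    if arr.min() < 0 or arr.max() > 2:
        raise ValueError("class map values must be in {0, 1, 2}")
    path = Path(path)
    data = arr.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_class_map(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path) if Path(path).suffix.lower() == ".png" else tifffile.imread(path))
    if arr.ndim != 2 or arr.min() < 0 or arr.max() > 2:
        raise ValueError(f"{path}: not a valid three-class map")
    return arr.astype(np.uint8)


def write_probability_maps(probs: ProbabilityMaps, path: str | Path) -> None:
    """Write probability maps as a 3-page float32 TIFF (inner, contour, background)."""
    tifffile.imwrite(
        Path(path), probs.to_stack().astype(np.float32), photometric="minisblack"
    )


def read_probability_maps(paths: str | Path | Sequence[str | Path]) -> ProbabilityMaps:
    """Read probability maps from one 3-page TIFF or three single-channel files.

    Validates range and per-pixel softmax sum; the error message for a
    sum violation names the worst pixel.
    """
    if isinstance(paths, (str, Path)):
        stack = np.asarray(tifffile.imread(Path(paths)), dtype=np.float64)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(
                f"{paths}: expected a 3-page TIFF (inner, contour, background), got shape {stack.shape}"
            )
    else:
        if len(paths) != 3:
            raise ValueError("expected exactly three channel files")
        pages = [np.asarray(tifffile.imread(Path(p)), dtype=np.float64) for p in paths]
        stack = np.stack(pages)
    return ProbabilityMaps.from_stack(stack)


def write_curve_csv(
    curves: Sequence[EvalCurve],
    path: str | Path,
    names: Sequence[str] | None = None,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Write per-image F1 curves (and mean/std rows) to CSV.

    Columns: image, threshold, TP, FN, FP, F1. With more than one curve
    and ``aggregate=True``, 'mean' and 'std' rows are appended.
    """
    from .evaluate import aggregate_curves

    if names is None:
        names = [f"image_{i}" for i in range(len(curves))]
    rows = []
    for name, c in zip(names, curves):
        for i, t in enumerate(c.thresholds):
            rows.append(
                {"image": name, "threshold": float(t), "TP": int(c.tp[i]),
                 "FN": int(c.fn[i]), "FP": int(c.fp[i]), "F1": float(c.f1[i])}
            )
    if aggregate and len(curves) > 1:
        t, mean, std = aggregate_curves(curves)
        for i, ti in enumerate(t):
            rows.append({"image": "mean", "threshold": float(ti), "TP": "",
                         "FN": "", "FP": "", "F1": float(mean[i])})
        for i, ti in enumerate(t):
            rows.append({"image": "std", "threshold": float(ti), "TP": "",
                         "FN": "", "FP": "", "F1": float(std[i])})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.10g")
    return df


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for the full instantiate -> fuse -> evaluate run."""

    seed_threshold: float = 0.35
    background_threshold: float = 0.95
    min_area: int = 35
    gap_dilation_radius: int = 1
    keep_overlap_min: float = 0.20
    add_overlap_max: float = 0.33
    threshold_step: float = 0.05
    master_seed: int = 0

    def postprocess_params(self) -> PostprocessParams:
        return PostprocessParams(
            seed_threshold=self.seed_threshold,
            background_threshold=self.background_threshold,
            min_area=self.min_area,
            gap_dilation_radius=self.gap_dilation_radius,
        )

    def fusion_params(self) -> FusionParams:
        return FusionParams(
            keep_overlap_min=self.keep_overlap_min,
            add_overlap_max=self.add_overlap_max,
            min_area=self.min_area,
        )

    def thresholds(self) -> np.ndarray:
        return default_thresholds(self.threshold_step)


def serialize_config(config: PipelineConfig) -> str:
    return "\n".join(f"{f.name}={getattr(config, f.name)}" for f in fields(config)) + "\n"


def parse_config(text: str) -> PipelineConfig:
    """Parse a key=value config; unknown keys raise, types follow the defaults."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"line {lineno}: unknown configuration key {key!r}")
        default = getattr(PipelineConfig(), key)
        kwargs[key] = type(default)(value.strip())
    return PipelineConfig(**kwargs)


def read_config(path: str | Path) -> PipelineConfig:
    return parse_config(Path(path).read_text())


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_config(config))


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(serialize_config(config).encode()).hexdigest()[:16]
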