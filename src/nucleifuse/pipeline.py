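"""End-to-end strategy run: instantiate -> fuse -> evaluate.

``run_strategy`` ties the stages together the way the segmentation
strategy uses them: the semantic network's probability maps are
post-processed into instances, fused with the instance network's
predictions, and (when ground truth is supplied) both individual and
fused results are scored with F1-vs-IoU curves. Every run writes a
plain-text log with the package version, a configuration hash and all
seeds, so results are reproducible from the log alone.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import EvalCurve, f1_curve
from .fuse import fuse_instances
from .instantiate import instances_from_probabilities
from .io import (
    PipelineConfig,
    config_hash,
    read_instance_map,
    read_probability_maps,
    write_curve_csv,
    write_instance_map,
)


class StageError(RuntimeError):
    """Error raised by one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class StrategyResult:
    semantic_instances: np.ndarray
    fused: np.ndarray
    curves: dict[str, EvalCurve]


def run_strategy(
    config: PipelineConfig,
    probs_path: str | Path,
    instance_path: str | Path,
    out_dir: str | Path,
    gt_path: str | Path | None = None,
) -> StrategyResult:
    """Execute the full pipeline on one image; write label maps, CSV and log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        probs = read_probability_maps(probs_path)
        instance_seg = read_instance_map(instance_path, normalize=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("read", e) from e

    try:
        semantic_instances = instances_from_probabilities(
            probs, config.postprocess_params()
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("instantiate", e) from e

    try:
        fused = fuse_instances(instance_seg, semantic_instances, config.fusion_params())
    except Exception as e:  # noqa: BLE001
        raise StageError("fuse", e) from e

    write_instance_map(semantic_instances, out_dir / "semantic_instances.tif")
    write_instance_map(fused, out_dir / "fused.tif")

    curves: dict[str, EvalCurve] = {}
    if gt_path is not None:
        try:
            gt = read_instance_map(gt_path, normalize=True)
            t = config.thresholds()
            curves["semantic"] = f1_curve(gt, semantic_instances, t)
            curves["instance"] = f1_curve(gt, instance_seg, t)
            curves["fused"] = f1_curve(gt, fused, t)
            write_curve_csv(
                list(curves.values()),
                out_dir / "metrics.csv",
                names=list(curves),
                aggregate=False,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("evaluate", e) from e

    log = [
        f"nucleifuse version: {__version__}",
        f"config hash: {config_hash(config)}",
        f"master seed: {config.master_seed}",
        f"probability maps: {probs_path}",
        f"instance segmentation: {instance_path}",
        f"ground truth: {gt_path}",
        f"timestamp: {datetime.datetime.now(datetime.timezone.utc).isoformat()}",
    ]
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return StrategyResult(semantic_instances=semantic_instances, fused=fused, curves=curves)
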