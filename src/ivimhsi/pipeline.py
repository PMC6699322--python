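"""End-to-end pipeline: cube -> body mask -> parameter maps -> band
expansion -> target detection -> thresholding -> tissue classification."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ivimhsi.bep import expand_bands
from ivimhsi.breastseg import extract_breast_region, integer_align
from ivimhsi.classify import DecisionThresholds, classify_map, default_thresholds, summarize_case
from ivimhsi.detect import KernelSpec, detect_lesions
from ivimhsi.io import (
    write_detection_map,
    write_label_map,
    write_label_overlay_png,
    write_mask,
    write_param_maps,
)
from ivimhsi.ivim_model import FitBounds, IVIMCube, compute_param_maps
from ivimhsi.threshold import local_entropy_threshold, otsu_threshold, quantize

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and cause."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    fit_method: str = "full"
    b_split: float = 250.0
    bounds: FitBounds = field(default_factory=FitBounds)
    bep_order: int = 2
    include_sqrt: bool = False
    include_log: bool = False
    normalize_bands: bool = False
    n_targets: int = 5
    angle_threshold: float = 0.05
    kernel: KernelSpec = field(default_factory=KernelSpec)
    ridge: object = "auto"
    background_subsample: int = 2000
    thresholder: str = "local_entropy"
    quantize_levels: int = 256
    thresholds: DecisionThresholds = field(default_factory=default_thresholds)
    split_mode: str = "fixed"
    align: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fit_method not in ("segmented", "full"):
            raise ValueError(f"unknown fit method {self.fit_method!r}")
        if self.bep_order not in (1, 2, 3):
            raise ValueError("bep_order must be 1, 2 or 3")
        if self.thresholder not in ("local_entropy", "otsu"):
            raise ValueError(f"unknown thresholder {self.thresholder!r}")
        if self.n_targets < 1:
            raise ValueError("need at least one target")
        if self.angle_threshold <= 0:
            raise ValueError("angle_threshold must be positive")
        if isinstance(self.kernel, dict):
            self.kernel = KernelSpec(**self.kernel)
        if isinstance(self.thresholds, dict):
            self.thresholds = DecisionThresholds(**self.thresholds)
        if isinstance(self.bounds, dict):
            self.bounds = FitBounds(**{k: tuple(v) for k, v in self.bounds.items()})


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig, cube: IVIMCube, out_dir=None) -> dict:
    """Run the full detection/classification chain on one cube.

    Returns a dict of artifacts: body_mask, param_maps, detection_map,
    threshold_level, lesion_mask, label_map, summary (DataFrame), targets,
    manifest.  Deterministic for a fixed (cfg, cube, cfg.seed); when
    ``out_dir`` is given every artifact is also written to disk along with a
    JSON manifest echoing the configuration.
    """
    timings: dict[str, float] = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        result = _stage(name, fn, *args, **kwargs)
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    if cfg.align:
        cube = timed("align", integer_align, cube)

    def body_mask_3d():
        mask = np.zeros(cube.spatial_shape, dtype=bool)
        for s in range(cube.spatial_shape[2]):
            mask[:, :, s], _ = extract_breast_region(cube.data[:, :, s, 0])
        return mask

    body_mask = timed("breastseg", body_mask_3d)
    maps = timed(
        "fit",
        compute_param_maps,
        cube,
        body_mask,
        method=cfg.fit_method,
        b_split=cfg.b_split,
        bounds=cfg.bounds,
    )
    bands = timed(
        "bep",
        expand_bands,
        cube,
        order=cfg.bep_order,
        include_sqrt=cfg.include_sqrt,
        include_log=cfg.include_log,
        normalize=cfg.normalize_bands,
    )
    detection_map, per_target_maps, targets = timed(
        "detect",
        detect_lesions,
        bands,
        n_targets=cfg.n_targets,
        angle_threshold=cfg.angle_threshold,
        kernel=cfg.kernel,
        ridge=cfg.ridge,
        background_subsample=cfg.background_subsample,
        seed=cfg.seed,
    )

    def threshold_map():
        q = quantize(detection_map, G=cfg.quantize_levels)
        thresholder = local_entropy_threshold if cfg.thresholder == "local_entropy" else otsu_threshold
        level, mask = thresholder(q)
        return level, mask & body_mask

    threshold_level, lesion_mask = timed("threshold", threshold_map)
    label_map = timed(
        "classify",
        classify_map,
        maps,
        cfg.thresholds,
        lesion_mask=None,
        split_mode=cfg.split_mode,
    )
    summary = timed("summarize", summarize_case, label_map, maps)

    from ivimhsi import __version__ as _version  # deferred: avoids import cycle

    manifest = {
        "version": _version,
        "seed": cfg.seed,
        "config": _jsonable(asdict(cfg)),
        "timings_s": timings,
        "threshold_level": int(threshold_level),
        "n_targets_found": len(targets),
    }
    artifacts = {
        "body_mask": body_mask,
        "param_maps": maps,
        "band_cube": bands,
        "detection_map": detection_map,
        "per_target_maps": per_target_maps,
        "targets": targets,
        "threshold_level": threshold_level,
        "lesion_mask": lesion_mask,
        "label_map": label_map,
        "summary": summary,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_artifacts(artifacts, Path(out_dir))
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_artifacts(artifacts: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask(artifacts["body_mask"], out_dir / "body_mask.nii.gz")
    write_mask(artifacts["lesion_mask"], out_dir / "lesion_mask.nii.gz")
    write_label_map(artifacts["label_map"], out_dir / "labels.nii.gz")
    write_detection_map(artifacts["detection_map"], out_dir / "detection.nii.gz")
    write_param_maps(artifacts["param_maps"], out_dir / "maps", label_map=artifacts["label_map"])
    artifacts["summary"].to_csv(out_dir / "summary.csv", index=False)
    lm = artifacts["label_map"]
    for s in range(lm.shape[2]):
        write_label_overlay_png(
            artifacts["detection_map"][:, :, s], lm[:, :, s], out_dir / f"overlay_slice{s:02d}.png"
        )
    targets = artifacts["targets"]
    (out_dir / "targets.json").write_text(
        json.dumps(
            {
                "indices": targets.indices.tolist(),
                "spatial_indices": targets.spatial_indices().tolist()
                if targets.spatial_shape
                else None,
                "signatures": targets.signatures.tolist(),
                "stop_reason": targets.stop_reason,
            }
        )
    )
    (out_dir / "manifest.json").write_text(json.dumps(artifacts["manifest"], indent=2))
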