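"""Config-driven end-to-end orchestration.

A run takes either a phantom description (stage preset or explicit tree
parameters) or an existing volume plus seeds, executes

    segment -> centerline -> tree statistics,

and writes a reproducible result bundle into the output directory:

* ``volume.nii.gz``      the analysed (or generated) volume
* ``roi.nii.gz``         the segmented ROI mask
* ``ground_truth.swc``   phantom mode only, with ``ground_truth_segments.csv``
* ``recovered.swc``      the resolved centerline tree + segment table CSV
* ``statistics.csv``     per-scope (median, maximum, count) rows
* ``qc.json``            skeleton/pruning/cycle counters and ROI volume
* ``manifest.json``      config hash, package version, seeds, tolerances

Reruns with an identical config produce byte-identical statistics tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centerline import centerline_tree
from .phantom import (IntensityModel, TreeSpec, fit_tree_to_grid,
                      generate_preset_tree, generate_tree, rasterize,
                      stage_preset)
from .segmentation import (DEFAULT_TOLERANCE, SeedPoint, ToleranceWindow,
                           region_grow_multiseed, roi_volume)
from .treestats import (LateralAxis, assign_generations, split_sides,
                        statistics_table)
from .volio import VoxelVolume, read_volume, write_segment_table, write_swc, \
    write_volume

__all__ = ["ConfigError", "StageError", "RunConfig", "run_pipeline"]

logger = logging.getLogger("vascmorph")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class RunConfig:
    """Validated run configuration; see the YAML schema in the README."""

    output_dir: Path
    seed: int = 0
    # phantom mode
    phantom_preset: Optional[str] = None  # e.g. "neonate-PA"
    phantom_spec: Optional[Dict[str, Any]] = None
    voxel_size_um: float = 30.0
    # input-volume mode
    input_volume: Optional[Path] = None
    seeds: List[Dict[str, Any]] = field(default_factory=list)
    root_point_mm: Optional[List[float]] = None
    # shared knobs
    label: str = "other"
    tolerance: float = DEFAULT_TOLERANCE
    connectivity: int = 26
    prune_factor: float = 2.0
    fill_cavities: bool = True
    side_axis: str = "x"
    side_positive: str = "left"

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        if "output_dir" not in raw:
            raise ConfigError("config requires 'output_dir'")
        cfg = cls(output_dir=Path(raw["output_dir"]),
                  seed=int(raw.get("seed", 0)))

        phantom = raw.get("phantom")
        inp = raw.get("input")
        if (phantom is None) == (inp is None):
            raise ConfigError(
                "config must provide exactly one of 'phantom' or 'input'"
            )
        if phantom is not None:
            cfg.phantom_preset = phantom.get("preset")
            cfg.phantom_spec = phantom.get("spec")
            if (cfg.phantom_preset is None) == (cfg.phantom_spec is None):
                raise ConfigError(
                    "phantom section needs exactly one of 'preset' or 'spec'"
                )
            cfg.voxel_size_um = float(phantom.get("voxel_size_um", 30.0))
            if cfg.voxel_size_um <= 0:
                raise ConfigError("voxel_size_um must be > 0")
        else:
            vol = inp.get("volume")
            if vol is None:
                raise ConfigError("input section requires 'volume'")
            cfg.input_volume = Path(vol)
            if not cfg.input_volume.exists():
                raise ConfigError(f"input volume not found: {vol}")
            cfg.seeds = list(inp.get("seeds", []))
            if not cfg.seeds:
                raise ConfigError("input mode requires at least one seed")
            if inp.get("root_point_mm") is None:
                raise ConfigError(
                    "input mode requires 'root_point_mm' (the trunk origin)"
                )
            cfg.root_point_mm = [float(v) for v in inp["root_point_mm"]]

        seg = raw.get("segmentation", {})
        cfg.label = seg.get("label", "other")
        cfg.tolerance = float(seg.get("tolerance", DEFAULT_TOLERANCE))
        cfg.connectivity = int(seg.get("connectivity", 26))
        if cfg.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if cfg.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")

        cl = raw.get("centerline", {})
        cfg.prune_factor = float(cl.get("prune_factor", 2.0))
        cfg.fill_cavities = bool(cl.get("fill_cavities", True))
        if cfg.prune_factor < 0:
            raise ConfigError("prune_factor must be >= 0")

        sides = raw.get("sides", {})
        cfg.side_axis = sides.get("axis", "x")
        cfg.side_positive = sides.get("positive", "left")
        if cfg.side_axis not in _AXES:
            raise ConfigError("sides.axis must be one of z, y, x")
        if cfg.side_positive not in ("left", "right"):
            raise ConfigError("sides.positive must be 'left' or 'right'")
        cfg._raw = raw  # kept for the manifest hash
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        raw = getattr(self, "_raw", {})
        canon = json.dumps(raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def _seed_point_in_lumen(tree, volume: VoxelVolume) -> SeedPoint:
    """A seed voxel at the midpoint of the root segment (inside the lumen)."""
    mid = tree.root.midpoint
    vs_mm = np.asarray(volume.voxel_size, float) / 1000.0
    idx = tuple(int(np.clip(m / v - 0.5, 0, s - 1))
                for m, v, s in zip(mid, vs_mm, volume.shape))
    return SeedPoint(index=idx)


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the configured run; returns paths and headline results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    axis = LateralAxis(axis=_AXES[config.side_axis],
                       positive=config.side_positive)
    qc: Dict[str, Any] = {}
    trees_for_stats = {}

    # ---- stage: acquire volume ---------------------------------------
    stage = "phantom" if config.input_volume is None else "load"
    try:
        if config.input_volume is None:
            if config.phantom_preset is not None:
                stage_name, vessel = config.phantom_preset.rsplit("-", 1)
                truth = generate_preset_tree(stage_preset(stage_name, vessel),
                                             seed=config.seed)
            else:
                spec = TreeSpec(**{**config.phantom_spec,
                                   "seed": config.seed})
                truth = generate_tree(spec)
            truth, shape = fit_tree_to_grid(truth, config.voxel_size_um,
                                            margin_um=6 * config.voxel_size_um)
            volume = rasterize(truth, shape, config.voxel_size_um,
                               IntensityModel(), seed=config.seed + 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                split_sides(assign_generations(truth), axis)
            trees_for_stats["ground_truth"] = truth
            seeds = [_seed_point_in_lumen(truth, volume)]
            # half a radius into the trunk: thinning can move the centerline
            # tip about one radius either way along the vessel axis
            root = truth.root
            u = (root.end - root.start) / np.linalg.norm(root.end - root.start)
            root_point = root.start + u * (0.5 * root.radius)
            write_volume(volume, out / "volume.nii.gz")
            write_swc(truth, out / "ground_truth.swc", label=config.label)
            write_segment_table(truth, out / "ground_truth_segments.csv")
        else:
            volume = read_volume(config.input_volume)
            seeds = [
                SeedPoint(index=tuple(int(i) for i in s["index"]),
                          reference_gray=s.get("reference_gray"))
                for s in config.seeds
            ]
            root_point = np.asarray(config.root_point_mm, float)
    except (ConfigError,) as exc:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    # ---- stage: segmentation -----------------------------------------
    t1 = time.time()
    try:
        roi = region_grow_multiseed(
            volume, seeds, ToleranceWindow(config.tolerance),
            connectivity=config.connectivity, label=config.label,
        )
        qc["roi_voxels"] = roi.voxel_count
        qc["roi_volume_mm3"] = roi_volume(roi, volume.voxel_size)
        write_volume(VoxelVolume(roi.mask.astype(np.uint16),
                                 volume.voxel_size, "roi"),
                     out / "roi.nii.gz")
    except Exception as exc:
        raise StageError("segment", str(exc)) from exc
    logger.info("stage segment done in %.2fs", time.time() - t1)

    # ---- stage: centerline + statistics ------------------------------
    t2 = time.time()
    try:
        recovered, cqc = centerline_tree(
            roi, volume.voxel_size, root_point,
            min_length_factor=config.prune_factor,
            fill_holes=config.fill_cavities,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            split_sides(assign_generations(recovered), axis)
        trees_for_stats["recovered"] = recovered
        qc.update(cqc)
        write_swc(recovered, out / "recovered.swc", label=config.label)
        write_segment_table(recovered, out / "recovered_segments.csv")
    except Exception as exc:
        raise StageError("centerline", str(exc)) from exc
    logger.info("stage centerline done in %.2fs", time.time() - t2)

    # ---- outputs ------------------------------------------------------
    stats = statistics_table(trees_for_stats)
    stats.insert(0, "source", stats.pop("tree"))
    stats_path = out / "statistics.csv"
    stats.to_csv(stats_path, index=False, float_format="%.6g",
                 lineterminator="\n")
    (out / "qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
    manifest = {
        "config_hash": config.config_hash(),
        "package": "vascmorph",
        "version": __version__,
        "seed": config.seed,
        "tolerance": config.tolerance,
        "connectivity": config.connectivity,
        "prune_factor": config.prune_factor,
        "voxel_size_um": list(volume.voxel_size),
        "label": config.label,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    logger.info("run finished in %.2fs", time.time() - t0)
    return {
        "statistics": stats,
        "statistics_path": stats_path,
        "qc": qc,
        "manifest": manifest,
        "output_dir": out,
    }
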