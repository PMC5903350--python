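"""End-to-end orchestration with a machine-readable run report.

A run takes one or two inputs (volume files or synthetic presets), pushes
each through enhance → segment → skeletonize → prune → VOI sampling → MVD,
and, when two inputs are given, compares their per-VOI centerline MVD
distributions with a two-sample t-test. Intermediate artifacts (mask,
skeleton, per-VOI tables) are always written so every stage can be
inspected visually, and every random decision is keyed by a recorded seed:
identical config + inputs give identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AngioMVDError
from .groupstats import t_test_two_sample
from .mvd import (
    mvd_centerline_3d,
    mvd_slice_count_2d,
    mvd_vessel_count_3d,
    mvd_voxel_fraction_3d,
)
from .skeleton import prune_skeleton, skeletonize_3d
from .synthvessel import generate_tree, load_presets, spec_from_preset
from .types import VOI, VolumeImage
from .vesselseg import EnhanceParams, segment_vessels
from .volio import read_volume, sample_vois, write_volume

__all__ = ["InputSpec", "RunConfig", "RunReport", "run_pipeline", "validate_config"]

_VERSION = "0.1.0"

_METHODS = ("centerline_3d", "slice_count_2d", "vessel_count_3d", "voxel_fraction_3d")


@dataclass
class InputSpec:
    """One input: a volume file OR a synthetic preset (exactly one)."""

    label: str = "sample"
    path: str | None = None
    format: str | None = None
    preset: str | None = None
    seed: int = 0


@dataclass
class RunConfig:
    inputs: list[InputSpec] = field(default_factory=list)
    out_dir: str = "angiomvd_run"
    # enhancement / segmentation
    enhance_mode: str = "hdome"
    h_frac: float = 0.1
    combine_weight: float = 1.0
    n_bins: int = 256
    # skeleton
    min_branch_len: int = 5
    # VOI sampling
    n_vois: int = 10
    voi_shape: tuple[int, int, int] = (100, 100, 100)
    voi_seed: int = 0
    # metrics
    methods: tuple[str, ...] = ("centerline_3d",)
    slice_indices: tuple[int, ...] = (10, 50)
    # comparison
    t_variant: str = "pooled"
    write_intermediates: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        inputs = [InputSpec(**i) for i in raw.pop("inputs", [])]
        cfg = cls(inputs=inputs, **raw)
        cfg.voi_shape = tuple(cfg.voi_shape)
        cfg.methods = tuple(cfg.methods)
        cfg.slice_indices = tuple(cfg.slice_indices)
        return cfg


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict
    per_voi: list[dict]
    comparisons: list[dict]
    seeds: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "stages": self.stages,
                "per_voi": self.per_voi,
                "comparisons": self.comparisons,
                "seeds": self.seeds,
            },
            indent=2,
            default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff :func:`run_pipeline` can start."""
    problems: list[str] = []
    if not config.inputs:
        problems.append("inputs: at least one input is required")
    if len(config.inputs) > 2:
        problems.append("inputs: at most two inputs (groups) are supported")
    known_presets = set(load_presets()["presets"])
    for i, inp in enumerate(config.inputs):
        has_path, has_preset = inp.path is not None, inp.preset is not None
        if has_path == has_preset:
            problems.append(f"inputs[{i}]: exactly one of path/preset must be set")
        if has_path and not Path(inp.path).exists():
            problems.append(f"inputs[{i}].path: file not found: {inp.path}")
        if has_preset and inp.preset not in known_presets:
            problems.append(f"inputs[{i}].preset: unknown preset {inp.preset!r}")
    if config.min_branch_len < 1:
        problems.append("min_branch_len: must be >= 1")
    if not 0 <= config.h_frac <= 1:
        problems.append("h_frac: must lie in [0, 1]")
    if not 0 <= config.combine_weight <= 1:
        problems.append("combine_weight: must lie in [0, 1]")
    if config.n_bins < 2:
        problems.append("n_bins: must be >= 2")
    if config.n_vois < 1:
        problems.append("n_vois: must be >= 1")
    if any(s < 1 for s in config.voi_shape):
        problems.append("voi_shape: all extents must be >= 1")
    for m in config.methods:
        if m not in _METHODS:
            problems.append(f"methods: unknown method {m!r}")
    if config.t_variant not in ("pooled", "welch"):
        problems.append("t_variant: must be 'pooled' or 'welch'")
    for inp in config.inputs:
        if inp.preset in known_presets and inp.path is None:
            dom = load_presets()["presets"][inp.preset]["domain_shape"]
            if any(v > d for v, d in zip(config.voi_shape, dom)):
                problems.append(
                    f"voi_shape: {tuple(config.voi_shape)} exceeds preset "
                    f"domain {tuple(dom)}"
                )
    return problems


def _load_input(inp: InputSpec) -> VolumeImage:
    if inp.preset is not None:
        return generate_tree(spec_from_preset(inp.preset, seed=inp.seed)).volume
    return read_volume(inp.path, format=inp.format)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write the run report.

    Any stage failure aborts with the stage name and cause; partial outputs
    stay on disk next to a ``FAILED`` marker file.
    """
    problems = validate_config(config)
    if problems:
        raise AngioMVDError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    per_voi: list[dict] = []
    comparisons: list[dict] = []
    group_values: dict[str, list[float]] = {}
    stage = "start"
    try:
        for gi, inp in enumerate(config.inputs):
            label = inp.label or f"group{gi}"
            stage = f"load[{label}]"
            volume = _load_input(inp)

            stage = f"segment[{label}]"
            params = EnhanceParams(
                mode=config.enhance_mode,
                h_frac=config.h_frac,
                combine_weight=config.combine_weight,
            )
            mask, seg_report = segment_vessels(volume, params, n_bins=config.n_bins)

            stage = f"skeleton[{label}]"
            skel = prune_skeleton(
                skeletonize_3d(mask), min_branch_len=config.min_branch_len
            )

            if config.write_intermediates:
                write_volume(
                    VolumeImage(mask.mask.astype(np.uint8), mask.voxel_size_um),
                    out / f"{label}_mask.tif",
                )
                write_volume(
                    VolumeImage(skel.mask.astype(np.uint8), skel.voxel_size_um),
                    out / f"{label}_skeleton.tif",
                )
                np.savetxt(
                    out / f"{label}_skeleton_voxels.csv",
                    skel.voxels,
                    fmt="%d",
                    delimiter=",",
                    header="z,y,x",
                    comments="",
                )

            stage = f"voi_sampling[{label}]"
            voi_seed = config.voi_seed + gi
            vois = sample_vois(
                volume.shape, n=config.n_vois, shape=config.voi_shape, seed=voi_seed
            )

            stage = f"mvd[{label}]"
            values: list[float] = []
            for voi in vois:
                for method in config.methods:
                    if method == "centerline_3d":
                        res = mvd_centerline_3d(skel, voi)
                    elif method == "vessel_count_3d":
                        res = mvd_vessel_count_3d(skel, voi)
                    elif method == "voxel_fraction_3d":
                        res = mvd_voxel_fraction_3d(mask, voi)
                    else:
                        for si in config.slice_indices:
                            r2 = mvd_slice_count_2d(mask, voi, si)
                            per_voi.append({"group": label, **r2.as_row()})
                        continue
                    per_voi.append({"group": label, **res.as_row()})
                    if method == "centerline_3d":
                        values.append(res.value)
            group_values[label] = values
            stages[label] = {
                "segmentation": seg_report,
                "skeleton_voxels": skel.n_voxels,
                "min_branch_len": config.min_branch_len,
                "voi_seed": voi_seed,
                "n_vois": len(vois),
            }

        if len(config.inputs) == 2 and all(
            len(v) >= 2 for v in group_values.values()
        ):
            stage = "comparison"
            (la, va), (lb, vb) = group_values.items()
            comp = t_test_two_sample(
                va, vb, variant=config.t_variant, label_a=la, label_b=lb,
                unit_of_analysis="VOI",
            )
            comparisons.append(comp.as_dict())
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc!r}\n")
        raise AngioMVDError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = RunReport(
        config={**asdict(config)},
        version=_VERSION,
        stages=stages,
        per_voi=per_voi,
        comparisons=comparisons,
        seeds={
            "voi_seed_base": config.voi_seed,
            "input_seeds": {i.label: i.seed for i in config.inputs},
        },
    )
    report.to_json(out / "report.json")
    if per_voi:
        pd.DataFrame(per_voi).to_csv(out / "per_voi.csv", index=False)
    return report
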