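"""End-to-end orchestration of the nuclear and profile branches.

On disk, one meristem = one directory with fixed file names::

    <input_dir>/<meristem>/image.tif    (nuclear branch: single-z image)
    <input_dir>/<meristem>/stack.tif    (profile branch: z-stack)
    <input_dir>/<meristem>/mask.png     (nuclear branch: label mask)
    <input_dir>/<meristem>/outline.csv  (traced dome outline)
    <input_dir>/<meristem>/meta.json    (meristem_id, time_point, ...)

so cohorts are globbable and each meristem is processed independently.
Both branches are fully deterministic: identical config + inputs give
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .geometry import fit_parabola, build_parabolic_mask, build_rectangular_mask, combine_masks
from .io import (
    ImageStack,
    LabelMask,
    OutlineTrace,
    SamQuantError,
    read_image_stack,
    read_label_mask,
    read_outline,
    write_image_stack,
    write_label_mask,
    write_outline,
)
from .profiles import normalize_profile, profile_along_axis, sum_projection
from .quantify import normalize_cohort, quantify_nuclei, summarize_cohort
from .regions import RegionSpec, build_partition
from .stats import pairwise_timepoints
from .synthetic import CohortMember, make_scene, render_scene

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    pixel_size_um: float = 0.5
    z_step_um: float = 1.0
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    bin_width_um: float = 10.0
    curvature_factor: float = 1.3
    alpha: float = 0.1
    baseline_time_point: str = "10LD"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "z_step_um", "bin_width_um", "curvature_factor"):
            if getattr(self, name) <= 0:
                raise SamQuantError(f"RunConfig.{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise SamQuantError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "region_spec" in d and isinstance(d["region_spec"], dict):
            d["region_spec"] = RegionSpec(**d["region_spec"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _discover_meristems(input_dir: Path, image_name: str) -> list[Path]:
    dirs = sorted(
        p for p in input_dir.iterdir() if p.is_dir() and (p / image_name).exists()
    )
    if not dirs:
        raise SamQuantError(f"no meristem directories with {image_name} under {input_dir}")
    return dirs


def _read_meta(mdir: Path) -> dict:
    meta_path = mdir / "meta.json"
    if meta_path.exists():
        return json.loads(meta_path.read_text())
    return {"meristem_id": mdir.name, "time_point": ""}


def analyze_nuclear_scene(
    stack: ImageStack,
    mask: LabelMask,
    outline: OutlineTrace,
    region_spec: RegionSpec,
    meristem_id: str = "m0",
    time_point: str = "",
) -> pd.DataFrame:
    """Single-meristem nuclear branch, in memory: fit, partition, quantify."""
    if mask.n_nuclei == 0:
        raise SamQuantError(f"meristem {meristem_id}: empty label mask")
    px = stack.pixel_size_um
    model = fit_parabola(outline, px)
    shape = stack.image_shape
    tissue = combine_masks(
        build_parabolic_mask(model, shape, px),
        build_rectangular_mask(model, shape, px),
    )
    partition = build_partition(model, region_spec, tissue, px)
    return quantify_nuclei(stack, mask, partition, meristem_id, time_point)


def analyze_nuclear_cohort(
    scenes: list[tuple[ImageStack, LabelMask, OutlineTrace, str, str]],
    region_spec: RegionSpec,
    baseline: str,
    alpha: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Nuclear branch over an in-memory cohort.

    ``scenes`` holds (stack, mask, outline, meristem_id, time_point)
    tuples.  Returns (nuclei, summaries, comparisons).
    """
    frames = [
        analyze_nuclear_scene(stack, mask, outline, region_spec, mid, tp)
        for stack, mask, outline, mid, tp in scenes
    ]
    nuclei = normalize_cohort(pd.concat(frames, ignore_index=True))
    summaries = summarize_cohort(nuclei)
    comparisons = pairwise_timepoints(summaries, baseline, alpha)
    return nuclei, summaries, comparisons


def analyze_synthetic_cohort(
    members: list[CohortMember],
    region_spec: RegionSpec | None = None,
    baseline: str = "10LD",
    alpha: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate, render and analyze a synthetic cohort end to end."""
    region_spec = region_spec or RegionSpec()
    scenes = []
    for m in members:
        truth = make_scene(m.spec, region_spec)
        stack, mask = render_scene(truth)
        scenes.append((stack, mask, truth.outline, m.meristem_id, m.time_point))
    return analyze_nuclear_cohort(scenes, region_spec, baseline, alpha)


def run_nuclear_branch(config: RunConfig) -> dict[str, Path]:
    """Disk-based nuclear branch: read meristem dirs, write CSVs + manifest."""
    t_start = time.perf_counter()
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, object] = {}
    scenes = []
    mdirs = _discover_meristems(input_dir, "image.tif")
    for mdir in mdirs:
        meta = _read_meta(mdir)
        mid = meta.get("meristem_id", mdir.name)
        t0 = time.perf_counter()
        stack = read_image_stack(
            mdir / "image.tif",
            meta.get("pixel_size_um", config.pixel_size_um),
            config.z_step_um,
            meta.get("channel_names"),
        )
        mask = read_label_mask(mdir / "mask.png")
        outline = read_outline(mdir / "outline.csv")
        scenes.append((stack, mask, outline, mid, meta.get("time_point", "")))
        logger.info("read %s (%.3fs)", mid, time.perf_counter() - t0)
    stage_counts["meristems"] = len(scenes)
    nuclei, summaries, comparisons = analyze_nuclear_cohort(
        scenes, config.region_spec, config.baseline_time_point, config.alpha
    )
    stage_counts["nuclei"] = int(len(nuclei))
    stage_counts["nuclei_outside_tissue"] = int((nuclei["region"] == "OUTSIDE").sum())
    stage_counts["comparisons"] = int(len(comparisons))
    paths = {
        "nuclei": out / "nuclei.csv",
        "summaries": out / "summaries.csv",
        "comparisons": out / "comparisons.csv",
        "manifest": out / "manifest.json",
    }
    nuclei.to_csv(paths["nuclei"], index=False)
    summaries.to_csv(paths["summaries"], index=False)
    comparisons.to_csv(paths["comparisons"], index=False)
    _write_manifest(paths["manifest"], config, "nuclear", stage_counts, t_start)
    return paths


def run_profile_branch(config: RunConfig) -> dict[str, Path]:
    """Disk-based profile branch: z-stacks + outlines -> per-bin profile CSV."""
    t_start = time.perf_counter()
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    stage_counts: dict[str, object] = {}
    mdirs = _discover_meristems(input_dir, "stack.tif")
    for mdir in mdirs:
        meta = _read_meta(mdir)
        mid = meta.get("meristem_id", mdir.name)
        try:
            stack = read_image_stack(
                mdir / "stack.tif",
                meta.get("pixel_size_um", config.pixel_size_um),
                config.z_step_um,
                meta.get("channel_names"),
            )
            outline = read_outline(mdir / "outline.csv")
            projected = sum_projection(stack)
            model = fit_parabola(outline, projected.pixel_size_um)
            bins = profile_along_axis(
                projected, model, config.curvature_factor, config.bin_width_um
            )
            bins = normalize_profile(bins)
        except SamQuantError as exc:
            raise SamQuantError(f"meristem {mid}: {exc}") from exc
        bins.insert(0, "meristem_id", mid)
        bins.insert(1, "time_point", meta.get("time_point", ""))
        frames.append(bins)
        logger.info("profiled %s: %d bins", mid, len(bins))
    profiles = pd.concat(frames, ignore_index=True)
    stage_counts["meristems"] = len(frames)
    stage_counts["bins"] = int(len(profiles))
    paths = {"profiles": out / "profiles.csv", "manifest": out / "manifest.json"}
    profiles.to_csv(paths["profiles"], index=False)
    _write_manifest(paths["manifest"], config, "profile", stage_counts, t_start)
    return paths


def _write_manifest(
    path: Path, config: RunConfig, branch: str, stage_counts: dict, t_start: float
) -> None:
    manifest = {
        "branch": branch,
        "samquant_version": __version__,
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def simulate_cohort(
    members: list[CohortMember],
    out_dir: str | Path,
    region_spec: RegionSpec | None = None,
) -> list[Path]:
    """Render a synthetic cohort to disk in the per-meristem layout."""
    region_spec = region_spec or RegionSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dirs = []
    for m in members:
        truth = make_scene(m.spec, region_spec)
        stack, mask = render_scene(truth)
        mdir = out / m.meristem_id
        mdir.mkdir(exist_ok=True)
        write_image_stack(stack, mdir / "image.tif")
        write_label_mask(mask, mdir / "mask.png")
        write_outline(truth.outline, mdir / "outline.csv")
        truth.nuclei_frame().to_csv(mdir / "truth.csv", index=False)
        (mdir / "meta.json").write_text(
            json.dumps(
                {
                    "meristem_id": m.meristem_id,
                    "time_point": m.time_point,
                    "pixel_size_um": m.spec.pixel_size_um,
                    "channel_names": m.spec.channels,
                    "seed": m.spec.seed,
                },
                indent=2,
                sort_keys=True,
            )
        )
        dirs.append(mdir)
    return dirs
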