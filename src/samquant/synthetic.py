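"""Synthetic SAM scene generation with exact ground truth.

Every downstream stage of the pipeline is exercised against scenes whose
geometry, zonation, nuclei and intensities are known by construction:

* the dome is a true tilted parabola, so the fitted model can be
  compared against generating parameters;
* nuclei are uniform-intensity disks (not Gaussian blobs), which makes
  per-nucleus total intensity and concentration ground truth *exact* and
  isolates quantification correctness from point-spread-function
  modelling;
* nucleus concentrations are quantized to multiples of 2**-20 so that
  every pixel sum and total/area division is exact in float64;
* all randomness flows from a single integer seed through
  ``numpy.random.SeedSequence``, so identical specs give bit-identical
  scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .geometry import ParabolaModel
from .io import ImageStack, LabelMask, OutlineTrace, SamQuantError
from .regions import RegionSpec, boundary_distance_px, build_partition

_QUANTUM = 2.0**-20  # concentration granularity: keeps float64 arithmetic exact


@dataclass(frozen=True)
class ChannelModel:
    """Mean nuclear concentration as a function of zone and time point.

    ``region_means`` gives the base mean per zone; ``time_factors``
    multiplies it at a given time point, restricted to ``time_regions``
    when that is set (e.g. an FT-like channel induced only in RM/OC at
    later time points).  ``cv`` is the per-nucleus coefficient of
    variation of the Gamma law the concentrations are drawn from.
    """

    region_means: Mapping[str, float]
    time_factors: Mapping[str, float] = field(default_factory=dict)
    time_regions: frozenset[str] | None = None
    cv: float = 0.15

    def mean(self, region: str, time_point: str) -> float:
        base = float(self.region_means[region])
        factor = float(self.time_factors.get(time_point, 1.0))
        if self.time_regions is not None and region not in self.time_regions:
            factor = 1.0
        return base * factor


def default_channel_models(ft_effect: float = 3.0) -> dict[str, ChannelModel]:
    """Two-channel model emulating an FD reporter (broadly expressed) and
    an FT reporter enriched in the rib meristem / organizing centre and
    induced at later time points."""
    return {
        "FD": ChannelModel(
            region_means={"CZ": 40.0, "OC": 60.0, "PZ": 55.0, "RM": 50.0}
        ),
        "FT": ChannelModel(
            region_means={"CZ": 6.0, "OC": 20.0, "PZ": 10.0, "RM": 25.0},
            time_factors={
                "11LD": ft_effect,
                "12LD": ft_effect,
                "13LD": ft_effect,
            },
            time_regions=frozenset({"RM", "OC"}),
        ),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Background offset plus additive Gaussian read noise; optional
    Poisson shot noise on the background."""

    background: float = 5.0
    gaussian_sd: float = 2.0
    poisson: bool = False

    @property
    def enabled(self) -> bool:
        return self.background > 0 or self.gaussian_sd > 0 or self.poisson


def no_noise() -> NoiseModel:
    return NoiseModel(background=0.0, gaussian_sd=0.0, poisson=False)


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of one synthetic meristem.

    Defaults describe a realistic mid-transition Arabidopsis SAM at
    confocal scale: a ~90 µm-wide dome (halfwidth 45 µm, curvature
    0.02 µm^-1, so the dome is ~40 µm deep at its edges), ~2.2 µm-radius
    nuclei, and 0.5 µm pixels on a 256x256 field.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    tilt_deg: float = 0.0
    apex_rc: tuple[float, float] = (40.0, 128.0)
    curvature_a: float = 0.02  # µm^-1
    dome_halfwidth_um: float = 45.0
    n_nuclei: int = 150
    nucleus_radius_um: tuple[float, float] = (2.2, 0.3)  # (mean, sd)
    channel_models: Mapping[str, ChannelModel] = field(
        default_factory=default_channel_models
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_z: int = 1
    outline_points: int = 61
    outline_jitter_px: float = 0.5
    time_point: str = "10LD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curvature_a <= 0:
            raise SamQuantError("curvature_a must be > 0")
        if self.dome_halfwidth_um <= 0:
            raise SamQuantError("dome_halfwidth_um must be > 0")
        if self.n_nuclei < 0:
            raise SamQuantError("n_nuclei must be >= 0")
        if self.pixel_size_um <= 0:
            raise SamQuantError("pixel_size_um must be > 0")

    @property
    def channels(self) -> list[str]:
        return list(self.channel_models)


@dataclass
class NucleusTruth:
    """Ground truth for one rendered nucleus."""

    nucleus_id: int
    centroid_rc: tuple[float, float]
    radius_um: float
    region: str
    area_px: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) of the rendered disk
    total_intensity: dict[str, float]
    concentration: dict[str, float]
    boundary_distance_px: float
    clipped: bool = False


@dataclass
class SceneTruth:
    """Everything the generator knows about a scene."""

    spec: SceneSpec
    region_spec: RegionSpec
    model: ParabolaModel
    outline: OutlineTrace
    nuclei: list[NucleusTruth]

    def nuclei_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nuclei:
            row = {
                "nucleus_id": n.nucleus_id,
                "centroid_row": n.centroid_rc[0],
                "centroid_col": n.centroid_rc[1],
                "radius_um": n.radius_um,
                "region": n.region,
                "area_px": n.area_px,
                "boundary_distance_px": n.boundary_distance_px,
            }
            for ch in self.spec.channels:
                row[f"total_{ch}"] = n.total_intensity[ch]
                row[f"concentration_{ch}"] = n.concentration[ch]
            rows.append(row)
        return pd.DataFrame(rows)


def true_model(spec: SceneSpec) -> ParabolaModel:
    """The generating parabola as a ParabolaModel (zero residual)."""
    hw = spec.dome_halfwidth_um
    return ParabolaModel(
        tilt_deg=spec.tilt_deg,
        apex_um=(
            spec.apex_rc[0] * spec.pixel_size_um,
            spec.apex_rc[1] * spec.pixel_size_um,
        ),
        curvature_a=spec.curvature_a,
        lateral_extent_um=(-hw, hw),
        base_depth_um=spec.curvature_a * hw * hw,
        rmse_um=0.0,
    )


def _region_of_point(
    x: float, d: float, model: ParabolaModel, spec: RegionSpec
) -> str:
    """Closed-form zone predicate at a continuous frame coordinate.

    Deliberately independent of the raster partition in
    :mod:`samquant.regions`, so truth labels and pipeline assignments
    are two separate routes to the same geometry.
    """
    x_min, x_max = model.lateral_extent_um
    in_dome = x_min <= x <= x_max and model.curvature_a * x * x <= d < model.base_depth_um
    in_rect = x_min <= x <= x_max and d >= model.base_depth_um
    if not (in_dome or in_rect):
        return "OUTSIDE"
    if abs(x) <= spec.cz_width_um / 2 and 0 <= d < spec.cz_height_um:
        return "CZ"
    oc_bot = spec.cz_height_um + spec.oc_height_um
    if abs(x) <= spec.oc_width_um / 2 and spec.cz_height_um <= d < oc_bot:
        return "OC"
    if d >= oc_bot:
        return "RM"
    return "PZ"


def sample_outline(spec: SceneSpec, rng: np.random.Generator) -> OutlineTrace:
    """Trace points sampled from the true parabola, with optional pixel jitter."""
    model = true_model(spec)
    xs = np.linspace(-spec.dome_halfwidth_um, spec.dome_halfwidth_um, spec.outline_points)
    ds = spec.curvature_a * xs * xs
    rows, cols = model.point_at(xs, ds, spec.pixel_size_um)
    pts = np.column_stack([rows, cols])
    if spec.outline_jitter_px > 0:
        pts = pts + rng.normal(0.0, spec.outline_jitter_px, pts.shape)
    return OutlineTrace(pts)


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr * dr + dc * dc <= radius_px * radius_px
    return dr[keep], dc[keep]


_MAX_PLACEMENT_ATTEMPTS = 10_000


def make_scene(spec: SceneSpec, region_spec: RegionSpec | None = None) -> SceneTruth:
    """Place non-overlapping nuclei in the tissue mask and fix their truth.

    Placement is rejection sampling on the tissue pixel grid with a
    10,000-attempt budget per nucleus (label masks must be unambiguous,
    so overlapping disks are never accepted).
    """
    region_spec = region_spec or RegionSpec()
    model = true_model(spec)
    px = spec.pixel_size_um
    shape = spec.image_shape
    parab = geometry.build_parabolic_mask(model, shape, px)
    rect = geometry.build_rectangular_mask(model, shape, px)
    tissue = geometry.combine_masks(parab, rect)
    partition = build_partition(model, region_spec, tissue, px)
    bdist = boundary_distance_px(partition)

    rng_place = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    tr, tc = np.nonzero(tissue)
    if spec.n_nuclei > 0 and tr.size == 0:
        raise SamQuantError("tissue mask is empty; cannot place nuclei")

    occupied = np.zeros(shape, dtype=bool)
    h, w = shape
    nuclei: list[NucleusTruth] = []
    mean_r, sd_r = spec.nucleus_radius_um
    for nid in range(1, spec.n_nuclei + 1):
        radius_um = max(float(rng_place.normal(mean_r, sd_r)), 0.4 * mean_r)
        dr, dc = _disk_offsets(radius_um / px)
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            k = int(rng_place.integers(tr.size))
            r0, c0 = int(tr[k]), int(tc[k])
            rs, cs = r0 + dr, c0 + dc
            if rs.min() < 0 or cs.min() < 0 or rs.max() >= h or cs.max() >= w:
                continue
            if occupied[rs, cs].any():
                continue
            break
        else:
            raise SamQuantError(
                f"could not place nucleus {nid}/{spec.n_nuclei} without overlap "
                f"within {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        occupied[rs, cs] = True
        x, d = model.axis_coords(np.float64(r0), np.float64(c0), px)
        region = _region_of_point(float(x), float(d), model, region_spec)
        conc: dict[str, float] = {}
        total: dict[str, float] = {}
        area = int(rs.size)
        for ch, cm in spec.channel_models.items():
            mean = cm.mean(region if region != "OUTSIDE" else "PZ", spec.time_point)
            shape_k = 1.0 / (cm.cv * cm.cv)
            draw = rng_place.gamma(shape_k, mean / shape_k)
            c = max(np.round(draw / _QUANTUM) * _QUANTUM, 16 * _QUANTUM)
            conc[ch] = float(c)
            total[ch] = float(c * area)
        nuclei.append(
            NucleusTruth(
                nucleus_id=nid,
                centroid_rc=(float(r0), float(c0)),
                radius_um=radius_um,
                region=region,
                area_px=area,
                pixels=(rs, cs),
                total_intensity=total,
                concentration=conc,
                boundary_distance_px=float(bdist[r0, c0]),
            )
        )

    rng_outline = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    outline = sample_outline(spec, rng_outline)
    return SceneTruth(spec, region_spec, model, outline, nuclei)


def render_scene(truth: SceneTruth) -> tuple[ImageStack, LabelMask]:
    """Rasterize a scene: uniform-intensity disks over a noisy background.

    With noise disabled the summed intensity over each nucleus's labelled
    pixels equals its true total intensity exactly.
    """
    spec = truth.spec
    h, w = spec.image_shape
    channels = spec.channels
    noise = spec.noise
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    data = np.zeros((len(channels), spec.n_z, h, w), dtype=np.float64)
    for ci in range(len(channels)):
        for z in range(spec.n_z):
            if noise.poisson:
                data[ci, z] = rng.poisson(noise.background, (h, w)).astype(np.float64)
            else:
                data[ci, z] += noise.background
            if noise.gaussian_sd > 0:
                data[ci, z] += rng.normal(0.0, noise.gaussian_sd, (h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    for n in truth.nuclei:
        rs, cs = n.pixels
        labels[rs, cs] = n.nucleus_id
        for ci, ch in enumerate(channels):
            for z in range(spec.n_z):
                vals = np.full(rs.size, n.concentration[ch] / spec.n_z)
                if noise.gaussian_sd > 0:
                    vals = vals + rng.normal(0.0, noise.gaussian_sd, rs.size)
                data[ci, z, rs, cs] = vals
    if noise.gaussian_sd > 0:
        np.maximum(data, 0.0, out=data)
    stack = ImageStack(data, spec.pixel_size_um, channel_names=list(channels))
    return stack, LabelMask(labels)


# ---------------------------------------------------------------------------
# profile-branch scenes


@dataclass
class ProfileSceneTruth:
    """Ground truth for a depth-profile z-stack scene.

    ``bins`` holds the expected concentration of each 10-µm (by default)
    depth section of the noise-free signal, accumulated pixel-by-pixel
    from the generating depth profile over the true curvature-scaled
    tissue mask.
    """

    spec: SceneSpec
    model: ParabolaModel
    outline: OutlineTrace
    bins: pd.DataFrame  # channel, bin_index, d_lo_um, d_hi_um, pixel_count, concentration
    curvature_factor: float
    bin_width_um: float


def make_profile_scene(
    spec: SceneSpec,
    depth_profile: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    curvature_factor: float = 1.3,
    bin_width_um: float = 10.0,
) -> tuple[ProfileSceneTruth, ImageStack]:
    """Render a z-stack whose sum projection follows ``depth_profile``.

    Each channel's noise-free signal at an in-mask pixel of depth ``d``
    is ``f(d)``, split evenly across the ``n_z`` slices; outside the
    curvature-scaled tissue mask the signal is zero.  Truth records the
    expected per-bin concentrations of the signal component (noise and
    background, when enabled, sit on top of it).
    """
    model = true_model(spec)
    px = spec.pixel_size_um
    shape = spec.image_shape
    scaled = geometry.scale_curvature(model, curvature_factor)
    mask = geometry.combine_masks(
        geometry.build_parabolic_mask(scaled, shape, px),
        geometry.build_rectangular_mask(scaled, shape, px),
    )
    if not mask.any():
        raise SamQuantError("curvature-scaled tissue mask is empty")
    _, d = geometry._frame_grids(scaled, shape, px)
    channels = list(depth_profile)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    noise = spec.noise

    h, w = shape
    data = np.zeros((len(channels), spec.n_z, h, w), dtype=np.float64)
    bin_rows = []
    d_in = np.maximum(d[mask], 0.0)  # boundary-tolerance pixels: first section
    idx = np.floor(d_in / bin_width_um).astype(np.int64)
    n_bins = int(idx.max()) + 1 if idx.size else 0
    counts = np.bincount(idx, minlength=n_bins)
    for ci, ch in enumerate(channels):
        signal = np.zeros((h, w), dtype=np.float64)
        signal[mask] = depth_profile[ch](d_in)
        if np.any(signal < 0):
            raise SamQuantError(f"depth profile for {ch} produced negative intensity")
        per_slice = signal / spec.n_z
        for z in range(spec.n_z):
            data[ci, z] = per_slice
            if noise.background > 0:
                data[ci, z] += noise.background / spec.n_z
            if noise.gaussian_sd > 0:
                data[ci, z] += rng.normal(0.0, noise.gaussian_sd, (h, w))
        totals = np.bincount(idx, weights=signal[mask], minlength=n_bins)
        for b in range(n_bins):
            bin_rows.append(
                {
                    "channel": ch,
                    "bin_index": b,
                    "d_lo_um": b * bin_width_um,
                    "d_hi_um": (b + 1) * bin_width_um,
                    "pixel_count": int(counts[b]),
                    "concentration": float(totals[b] / counts[b])
                    if counts[b]
                    else np.nan,
                }
            )
    if noise.gaussian_sd > 0:
        np.maximum(data, 0.0, out=data)
    rng_outline = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    outline = sample_outline(spec, rng_outline)
    stack = ImageStack(data, px, channel_names=channels)
    truth = ProfileSceneTruth(
        spec, model, outline, pd.DataFrame(bin_rows), curvature_factor, bin_width_um
    )
    return truth, stack


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortMember:
    meristem_id: str
    time_point: str
    spec: SceneSpec


def make_cohort(
    design: Sequence[tuple[str, int]],
    seed: int,
    base_spec: SceneSpec | None = None,
    channel_models: Mapping[str, ChannelModel] | None = None,
) -> list[CohortMember]:
    """Expand a cohort design into per-meristem scene specs.

    ``design`` is a list of ``(time_point, n_meristems)`` pairs, e.g. the
    3/4/4/4 meristems at 10/11/12/13 long days used for the nuclear
    branch.  Each meristem receives an independent sub-seed spawned from
    ``seed``, so cohorts are reproducible while meristems stay
    statistically independent.
    """
    if not design:
        raise SamQuantError("cohort design must be nonempty")
    base = base_spec or SceneSpec()
    if channel_models is not None:
        base = replace(base, channel_models=channel_models)
    n_total = sum(n for _, n in design)
    children = np.random.SeedSequence(seed).spawn(n_total)
    members: list[CohortMember] = []
    i = 0
    for time_point, n in design:
        for k in range(n):
            sub_seed = int(children[i].generate_state(1, dtype=np.uint32)[0] % (2**31))
            members.append(
                CohortMember(
                    meristem_id=f"{time_point}_m{k}",
                    time_point=time_point,
                    spec=replace(base, time_point=time_point, seed=sub_seed),
                )
            )
            i += 1
    return members


TIMECOURSE_DESIGN: tuple[tuple[str, int], ...] = (
    ("10LD", 3),
    ("11LD", 4),
    ("12LD", 4),
    ("13LD", 4),
)
"""Cohort layout of the nuclear time course: 3, 4, 4 and 4 meristems at
10, 11, 12 and 13 long days."""
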