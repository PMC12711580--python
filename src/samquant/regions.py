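"""Partition of the meristem tissue mask into functional zones.

The four zones are defined geometrically in the tilt-corrected frame with
the apex at the origin (``x`` lateral, ``d`` depth):

* CZ (central zone):      ``|x| <= cz_width/2``, ``0 <= d < cz_height``
* OC (organizing centre): ``|x| <= oc_width/2``,
  ``cz_height <= d < cz_height + oc_height``
* RM (rib meristem):      ``d >= cz_height + oc_height``
* PZ (peripheral zone):   every remaining tissue pixel, between CZ/OC and
  the fitted parabola.

All four are intersected with the tissue mask; depth boundaries are
half-open so the zones tile without overlap.  The CZ box dimensions proxy
the CLV3 expression domain and the OC box the WUS domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .geometry import ParabolaModel, _frame_grids
from .io import SamQuantError

OUTSIDE, CZ, OC, PZ, RM = 0, 1, 2, 3, 4
REGION_NAMES = {OUTSIDE: "OUTSIDE", CZ: "CZ", OC: "OC", PZ: "PZ", RM: "RM"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}
TISSUE_REGIONS = ("CZ", "OC", "PZ", "RM")


@dataclass(frozen=True)
class RegionSpec:
    """Zone box dimensions (µm); defaults follow typical Arabidopsis
    CLV3 (central zone) and WUS (organizing centre) domain sizes and are
    meant to be overridden from the run config."""

    cz_width_um: float = 30.0
    cz_height_um: float = 25.0
    oc_width_um: float = 45.0
    oc_height_um: float = 25.0

    def __post_init__(self) -> None:
        for name in ("cz_width_um", "cz_height_um", "oc_width_um", "oc_height_um"):
            if getattr(self, name) <= 0:
                raise SamQuantError(f"RegionSpec.{name} must be > 0")


@dataclass
class RegionPartition:
    """Raster assignment of every pixel to CZ/OC/PZ/RM or OUTSIDE."""

    regions: np.ndarray  # uint8 raster of region codes
    model: ParabolaModel
    spec: RegionSpec
    pixel_size_um: float

    def areas_px(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.regions == code))
            for code, name in REGION_NAMES.items()
        }


def build_partition(
    model: ParabolaModel,
    spec: RegionSpec,
    tissue_mask: np.ndarray,
    pixel_size_um: float,
) -> RegionPartition:
    """Label every tissue pixel with its zone; non-tissue pixels are OUTSIDE."""
    x, d = _frame_grids(model, tissue_mask.shape, pixel_size_um)
    dome_halfwidth = max(-model.lateral_extent_um[0], model.lateral_extent_um[1])
    if spec.cz_width_um / 2 > dome_halfwidth or spec.oc_width_um / 2 > dome_halfwidth:
        warnings.warn(
            "region boxes are wider than the traced dome; CZ/OC will be "
            "clipped by the tissue mask",
            stacklevel=2,
        )
    t = tissue_mask
    cz = t & (np.abs(x) <= spec.cz_width_um / 2) & (d >= 0) & (d < spec.cz_height_um)
    oc_top, oc_bot = spec.cz_height_um, spec.cz_height_um + spec.oc_height_um
    oc = t & (np.abs(x) <= spec.oc_width_um / 2) & (d >= oc_top) & (d < oc_bot)
    rm = t & (d >= oc_bot)
    pz = t & ~(cz | oc | rm)
    regions = np.zeros(t.shape, dtype=np.uint8)
    regions[cz] = CZ
    regions[oc] = OC
    regions[pz] = PZ
    regions[rm] = RM
    return RegionPartition(regions, model, spec, pixel_size_um)


def assign_region(centroid_rc: tuple[float, float], partition: RegionPartition) -> str:
    """Region name at the pixel containing a nucleus centroid.

    The containing pixel of a point ``(r, c)`` is ``(floor(r + 1/2),
    floor(c + 1/2))`` (pixel centers sit on the integer grid, pixels are
    half-open boxes around them).
    """
    r, c = centroid_rc
    i = int(np.floor(r + 0.5))
    j = int(np.floor(c + 0.5))
    h, w = partition.regions.shape
    if not (0 <= i < h and 0 <= j < w):
        raise SamQuantError(f"centroid {centroid_rc} is outside the image bounds")
    return REGION_NAMES[int(partition.regions[i, j])]


def boundary_distance_px(partition: RegionPartition) -> np.ndarray:
    """Per-pixel lower bound on the distance (px) to the nearest region boundary.

    Computed as the Euclidean distance transform within each label minus
    one pixel: any point of a pixel whose transform value is ``k`` is at
    least ``k - 1`` pixels away from territory of a different label.
    """
    regions = partition.regions
    out = np.zeros(regions.shape, dtype=np.float64)
    for code in np.unique(regions):
        inside = regions == code
        out[inside] = distance_transform_edt(inside)[inside]
    return out - 1.0
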