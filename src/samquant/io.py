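"""Shared conventions and file I/O for the pipeline.

Coordinate conventions used throughout the package:

* Rasters are indexed ``(row, col)``, 0-based, with the row index
  increasing downward; the "inferior edge" of an image is its maximal
  row.  Pixel ``(0, 0)`` is the *center* of the top-left pixel.
* A pixel belongs to a mask iff its center satisfies the mask predicate.
* Physical distances are measured on the pixel-center grid;
  one pixel covers ``pixel_size_um ** 2`` square micrometres.
* Intervals on rasters and depth bins are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class SamQuantError(Exception):
    """Base class for errors raised by samquant."""


@dataclass
class ImageStack:
    """Multi-channel intensity raster indexed ``(channel, z, row, col)``.

    Intensities are stored as nonnegative float64.  2D images and
    single-channel z-stacks are represented with singleton axes so every
    downstream operation sees the same 4D layout.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise SamQuantError(
                f"ImageStack data must be (C, Z, Y, X); got ndim={self.data.ndim}"
            )
        if self.pixel_size_um <= 0:
            raise SamQuantError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.z_step_um <= 0:
            raise SamQuantError(f"z_step_um must be > 0, got {self.z_step_um}")
        if np.any(self.data < 0):
            raise SamQuantError("intensities must be nonnegative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise SamQuantError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


@dataclass
class LabelMask:
    """Integer nucleus-label raster: 0 = background, k > 0 = nucleus k.

    Labels need not be consecutive.  The raster must share its
    ``(row, col)`` shape with the image it annotates.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SamQuantError(f"label mask must be 2D, got ndim={self.labels.ndim}")
        if self.labels.size == 0:
            raise SamQuantError("label mask is empty")
        if not np.issubdtype(self.labels.dtype, np.integer):
            flat = self.labels
            if not np.all(np.equal(np.mod(flat, 1), 0)):
                raise SamQuantError("label mask contains non-integer pixel values")
            self.labels = flat.astype(np.int64)
        if np.any(self.labels < 0):
            raise SamQuantError("label mask contains negative labels")

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_nuclei(self) -> int:
        return int(self.ids.size)


@dataclass
class OutlineTrace:
    """User-traced dome outline: ordered ``(row, col)`` pixel coordinates."""

    points: np.ndarray  # (N, 2) float, columns (row, col)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise SamQuantError("outline points must be an (N, 2) array of (row, col)")
        if self.points.shape[0] < 5:
            raise SamQuantError(
                f"outline needs >= 5 points (tilted-parabola fit has 4 free "
                f"parameters), got {self.points.shape[0]}"
            )
        cols = self.points[:, 1]
        if cols.max() - cols.min() <= 0:
            raise SamQuantError("outline has zero lateral extent (all points in one column)")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def read_image_stack(
    path: str | Path,
    pixel_size_um: float,
    z_step_um: float = 1.0,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF as an ImageStack, promoting missing axes.

    A 2D file is read as ``(1, 1, Y, X)``, a 3D file as ``(1, Z, Y, X)``
    and a 4D file as ``(C, Z, Y, X)``.  Intensities are preserved exactly
    (integer and float32 data embed losslessly in float64).
    """
    if pixel_size_um <= 0:
        raise SamQuantError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise SamQuantError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        arr = arr[np.newaxis]
    elif arr.ndim != 4:
        raise SamQuantError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    return ImageStack(arr, pixel_size_um, z_step_um, list(channel_names or []))


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the full (C, Z, Y, X) float64 raster to TIFF (lossless round-trip)."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def read_label_mask(path: str | Path) -> LabelMask:
    """Read a Cellpose-style label mask from PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = iio.imread(path)
    else:
        arr = tifffile.imread(str(path))
    return LabelMask(arr)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    path = Path(path)
    labels = mask.labels
    if path.suffix.lower() == ".png":
        if labels.max(initial=0) > np.iinfo(np.uint16).max:
            raise SamQuantError("labels exceed 16-bit range; write a TIFF instead")
        iio.imwrite(path, labels.astype(np.uint16))
    else:
        tifffile.imwrite(str(path), labels.astype(np.int32))


def read_outline(path: str | Path) -> OutlineTrace:
    """Read an outline trace from CSV (columns row, col) or JSON ([[row, col], ...])."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=np.float64)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if {"row", "col"} <= set(df.columns):
            pts = df[["row", "col"]].to_numpy(dtype=np.float64)
        else:  # headerless two-column file
            df = pd.read_csv(path, header=None, float_precision="round_trip")
            pts = df.to_numpy(dtype=np.float64)
    return OutlineTrace(pts)


def write_outline(trace: OutlineTrace, path: str | Path) -> None:
    pd.DataFrame(trace.points, columns=["row", "col"]).to_csv(path, index=False)
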