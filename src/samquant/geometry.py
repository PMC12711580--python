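"""Tilt-corrected parabolic parametrization of the SAM dome.

The dome outline is modelled as a parabola ``d = a * x**2`` in a rotated
("tilt-corrected") frame whose origin is the dome apex: ``x`` is the
signed lateral offset (µm) from the symmetry axis and ``d`` is the depth
(µm) below the apex along the axis.  ``tilt_deg`` is the rotation of the
symmetry axis away from image-vertical, positive clockwise in display
orientation (row down, col right).

With physical coordinates ``X = col * pixel_size`` and
``Y = row * pixel_size`` the frame axes are::

    lateral x-hat = ( cos(t),  sin(t))      (X, Y) components
    depth   d-hat = (-sin(t),  cos(t))

so a point maps to ``x = dX cos + dY sin`` and ``d = -dX sin + dY cos``
relative to the apex.  No image resampling is ever performed: depth and
lateral coordinates are evaluated exactly at pixel centers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import OutlineTrace, SamQuantError


class FitError(SamQuantError):
    """Raised when the parabolic fit fails or degenerates."""


@dataclass(frozen=True)
class ParabolaModel:
    """Fitted tilt-corrected parabola.

    Attributes
    ----------
    tilt_deg:
        Rotation of the dome symmetry axis from image-vertical,
        positive clockwise in display orientation.
    apex_um:
        Apex position ``(row_um, col_um)`` in physical coordinates.
    curvature_a:
        Parabola coefficient ``a`` (µm^-1) of ``d = a * x**2``.
    lateral_extent_um:
        ``(x_min, x_max)`` spanned by the input trace, relative to the
        apex; the apex is interior, so ``x_min < 0 < x_max``.
    base_depth_um:
        Depth of the deeper of the two trace endpoints.  The parabolic
        mask covers depths ``[a x**2, base_depth)``; the rectangular
        mask continues from ``base_depth`` to the inferior image edge.
    rmse_um:
        Root-mean-square depth residual of the fit.
    """

    tilt_deg: float
    apex_um: tuple[float, float]
    curvature_a: float
    lateral_extent_um: tuple[float, float]
    base_depth_um: float
    rmse_um: float

    def axis_coords(
        self, rows: np.ndarray, cols: np.ndarray, pixel_size_um: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel coordinates to (lateral x, depth d) in µm."""
        t = np.deg2rad(self.tilt_deg)
        dX = np.asarray(cols, dtype=np.float64) * pixel_size_um - self.apex_um[1]
        dY = np.asarray(rows, dtype=np.float64) * pixel_size_um - self.apex_um[0]
        x = dX * np.cos(t) + dY * np.sin(t)
        d = -dX * np.sin(t) + dY * np.cos(t)
        return x, d

    def point_at(self, x: np.ndarray, d: np.ndarray, pixel_size_um: float):
        """Inverse of :meth:`axis_coords`: frame coords -> (row, col) pixels."""
        t = np.deg2rad(self.tilt_deg)
        X = self.apex_um[1] + np.asarray(x) * np.cos(t) - np.asarray(d) * np.sin(t)
        Y = self.apex_um[0] + np.asarray(x) * np.sin(t) + np.asarray(d) * np.cos(t)
        return Y / pixel_size_um, X / pixel_size_um


def _rotated_lsq(X: np.ndarray, Y: np.ndarray, tilt_deg: float):
    """Least-squares parabola in the frame rotated by ``tilt_deg``.

    Returns (sse, coeffs) where coeffs = (A, B, C) of v = A u^2 + B u + C
    with u, v the rotated absolute coordinates.
    """
    t = np.deg2rad(tilt_deg)
    u = X * np.cos(t) + Y * np.sin(t)
    v = -X * np.sin(t) + Y * np.cos(t)
    design = np.column_stack([u * u, u, np.ones_like(u)])
    coeffs, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ coeffs
    return float(resid @ resid), coeffs, u, v


def fit_parabola(trace: OutlineTrace, pixel_size_um: float) -> ParabolaModel:
    """Fit a tilted parabola to a traced dome outline.

    The tilt is found by a deterministic bounded scalar search on
    [-45°, 45°] (coarse grid then local refinement); for each candidate
    tilt the parabola coefficients are the closed-form least-squares
    solution in the rotated frame, so the whole fit is seed-free.
    """
    if pixel_size_um <= 0:
        raise SamQuantError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    pts = trace.points
    Y = pts[:, 0] * pixel_size_um
    X = pts[:, 1] * pixel_size_um

    grid = np.linspace(-45.0, 45.0, 181)
    sses = np.array([_rotated_lsq(X, Y, t)[0] for t in grid])
    t0 = grid[int(np.argmin(sses))]
    lo, hi = max(-45.0, t0 - 1.0), min(45.0, t0 + 1.0)
    res = minimize_scalar(
        lambda t: _rotated_lsq(X, Y, t)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    tilt = float(res.x)
    sse, (A, B, C), u, v = _rotated_lsq(X, Y, tilt)

    if A <= 1e-12:
        raise FitError(
            f"parabola fit degenerated (curvature {A:.3g} <= 0) on trace with "
            f"{len(trace)} points; the outline may be collinear"
        )
    u0 = -B / (2.0 * A)
    v0 = C - B * B / (4.0 * A)
    t = np.deg2rad(tilt)
    apex_X = u0 * np.cos(t) - v0 * np.sin(t)
    apex_Y = u0 * np.sin(t) + v0 * np.cos(t)

    x_off = u - u0
    x_min, x_max = float(x_off.min()), float(x_off.max())
    if not (x_min < 0.0 < x_max):
        raise FitError(
            "fitted apex falls outside the traced lateral extent "
            f"[{x_min:.2f}, {x_max:.2f}] µm; the trace does not cover the dome tip"
        )
    # depth of the deeper trace endpoint (measured, not fitted)
    d_ends = (v[0] - v0, v[-1] - v0)
    base_depth = float(max(d_ends))
    rmse = float(np.sqrt(sse / len(trace)))
    return ParabolaModel(
        tilt_deg=tilt,
        apex_um=(float(apex_Y), float(apex_X)),
        curvature_a=float(A),
        lateral_extent_um=(x_min, x_max),
        base_depth_um=base_depth,
        rmse_um=rmse,
    )


def _frame_grids(model: ParabolaModel, shape: tuple[int, int], pixel_size_um: float):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return model.axis_coords(rows, cols, pixel_size_um)


# Membership tolerance for pixel centers lying exactly on the dome
# boundary (e.g. the apex): 1 nm, far below any pixel size.  Applied
# only to the parabola-side and lateral conditions — the parabolic/
# rectangular seam at base_depth stays exact, keeping the two masks
# disjoint.
_BOUNDARY_EPS_UM = 1e-9


def build_parabolic_mask(
    model: ParabolaModel, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Boolean raster of the dome interior.

    A pixel is in-mask iff, in the tilt-corrected frame, its center has
    ``x`` within the traced lateral extent and depth on the tissue side
    of the dome boundary: ``a x**2 <= d < base_depth``.
    """
    x, d = _frame_grids(model, shape, pixel_size_um)
    x_min, x_max = model.lateral_extent_um
    eps = _BOUNDARY_EPS_UM
    return (
        (x >= x_min - eps)
        & (x <= x_max + eps)
        & (d >= model.curvature_a * x * x - eps)
        & (d < model.base_depth_um)
    )


def build_rectangular_mask(
    model: ParabolaModel, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Boolean raster extending from the parabola ends to the inferior image edge.

    Covers ``x`` in the traced lateral extent and depths ``>= base_depth``,
    i.e. everything below the dome down to the bottom of the image.  The
    half-open depth boundary makes it tile seamlessly with the parabolic
    mask.
    """
    x, d = _frame_grids(model, shape, pixel_size_um)
    x_min, x_max = model.lateral_extent_um
    eps = _BOUNDARY_EPS_UM
    return (x >= x_min - eps) & (x <= x_max + eps) & (d >= model.base_depth_um)


def combine_masks(parabolic: np.ndarray, rectangular: np.ndarray) -> np.ndarray:
    """Logical union of the parabolic and rectangular masks (the tissue mask)."""
    if parabolic.shape != rectangular.shape:
        raise SamQuantError(
            f"mask shape mismatch: {parabolic.shape} vs {rectangular.shape}"
        )
    return parabolic | rectangular


def scale_curvature(model: ParabolaModel, factor: float) -> ParabolaModel:
    """Return a model with curvature multiplied by ``factor`` (>= 1).

    Apex, tilt, lateral extent and base depth are unchanged, so the
    scaled parabolic mask is a subset of the original one.
    """
    if factor < 1.0:
        raise SamQuantError(f"curvature scale factor must be >= 1, got {factor}")
    return dataclasses.replace(model, curvature_a=model.curvature_a * factor)
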