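"""Per-nucleus intensity quantification and cross-meristem normalization.

The central quantity is the nuclear *concentration*: total pixel
intensity within a segmented nucleus divided by its pixel area.  Area is
deliberately a pixel count, not µm²; the global pixel-size factor
cancels when concentrations are normalized by the cohort-wide maximum,
which also removes detector units.

Nuclei whose centroid falls outside the tissue mask keep their records
(region "OUTSIDE") but are excluded from normalization and summaries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ImageStack, LabelMask, SamQuantError
from .regions import RegionPartition, TISSUE_REGIONS, assign_region

logger = logging.getLogger(__name__)

SUMMARY_REGIONS = TISSUE_REGIONS + ("ALL",)


def quantify_nuclei(
    stack: ImageStack,
    mask: LabelMask,
    partition: RegionPartition,
    meristem_id: str = "m0",
    time_point: str = "",
) -> pd.DataFrame:
    """One record per labelled nucleus: area, centroid, totals, concentrations.

    total intensity = sum of channel intensity over the nucleus's
    labelled pixels; area = labelled pixel count; centroid = unweighted
    mean of labelled pixel coordinates; region = partition label at the
    pixel containing the centroid.
    """
    labels = mask.labels
    if labels.shape != stack.image_shape:
        raise SamQuantError(
            f"label mask shape {labels.shape} != image shape {stack.image_shape}"
        )
    if labels.shape != partition.regions.shape:
        raise SamQuantError(
            f"label mask shape {labels.shape} != partition shape "
            f"{partition.regions.shape}"
        )
    if stack.n_z != 1:
        raise SamQuantError(
            f"quantify_nuclei expects a single-z (or pre-projected) stack, "
            f"got Z={stack.n_z}"
        )
    ids = mask.ids
    flat = labels.ravel()
    minlength = int(labels.max()) + 1 if ids.size else 1
    areas = np.bincount(flat, minlength=minlength)
    rows_grid, cols_grid = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    row_sums = np.bincount(flat, weights=rows_grid.ravel(), minlength=minlength)
    col_sums = np.bincount(flat, weights=cols_grid.ravel(), minlength=minlength)

    records = []
    px2 = partition.pixel_size_um**2
    totals_per_channel = {
        ch: np.bincount(
            flat, weights=stack.data[ci, 0].ravel(), minlength=minlength
        )
        for ci, ch in enumerate(stack.channel_names)
    }
    for nid in ids:
        area = int(areas[nid])
        cr = row_sums[nid] / area
        cc = col_sums[nid] / area
        rec = {
            "meristem_id": meristem_id,
            "time_point": time_point,
            "nucleus_id": int(nid),
            "centroid_row": cr,
            "centroid_col": cc,
            "area_px": area,
            "area_um2": area * px2,
            "region": assign_region((cr, cc), partition),
        }
        for ch in stack.channel_names:
            total = float(totals_per_channel[ch][nid])
            rec[f"total_{ch}"] = total
            rec[f"concentration_{ch}"] = total / area
        records.append(rec)
    df = pd.DataFrame(records)
    if len(df):
        n_out = int((df["region"] == "OUTSIDE").sum())
        if n_out:
            logger.info(
                "%s: %d/%d nuclei have centroids outside the tissue mask "
                "(kept in output, excluded from summaries)",
                meristem_id,
                n_out,
                len(df),
            )
    return df


def channel_names_of(records: pd.DataFrame) -> list[str]:
    return [c[len("concentration_"):] for c in records.columns
            if c.startswith("concentration_")]


def normalize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_<channel>`` columns: concentration / cohort-wide max.

    The maximum is taken per channel over all in-tissue records of *all*
    meristems, so exactly the record(s) achieving it map to 1.0 and
    every normalized concentration lies in [0, 1].  An all-zero channel
    is left at 0 with a warning.  Idempotent on normalized data.
    """
    out = records.copy()
    in_tissue = out["region"] != "OUTSIDE"
    for ch in channel_names_of(records):
        conc = out[f"concentration_{ch}"]
        max_c = conc[in_tissue].max() if in_tissue.any() else 0.0
        if not np.isfinite(max_c) or max_c <= 0:
            warnings.warn(
                f"channel {ch} has no positive concentration; normalization "
                "skipped (normalized set to 0)",
                stacklevel=2,
            )
            out[f"normalized_{ch}"] = 0.0
        else:
            out[f"normalized_{ch}"] = conc / max_c
    return out


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return float(q1), float(med), float(q3)


def summarize_meristem(records: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of normalized concentrations for one meristem.

    One row per channel x region (the four zones plus a whole-SAM "ALL"
    row); quartiles use linear interpolation.  Regions without nuclei
    are emitted with ``n_nuclei = 0`` so summaries stay alignable across
    meristems.
    """
    if records.empty:
        raise SamQuantError("summarize_meristem: no records")
    mids = records["meristem_id"].unique()
    if len(mids) != 1:
        raise SamQuantError(f"summarize_meristem: expected one meristem, got {mids}")
    channels = channel_names_of(records)
    for ch in channels:
        if f"normalized_{ch}" not in records.columns:
            raise SamQuantError("records must be normalized first (normalize_cohort)")
    in_tissue = records[records["region"] != "OUTSIDE"]
    rows = []
    for ch in channels:
        for region in SUMMARY_REGIONS:
            sub = in_tissue if region == "ALL" else in_tissue[in_tissue["region"] == region]
            vals = sub[f"normalized_{ch}"].to_numpy()
            if vals.size:
                q1, med, q3 = _quartiles(vals)
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    "meristem_id": mids[0],
                    "time_point": records["time_point"].iloc[0],
                    "channel": ch,
                    "region": region,
                    "n_nuclei": int(vals.size),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-meristem summaries for a whole cohort (concatenated)."""
    frames = [
        summarize_meristem(records[records["meristem_id"] == mid])
        for mid in pd.unique(records["meristem_id"])
    ]
    return pd.concat(frames, ignore_index=True)


def intensity_variation(profile) -> float:
    """Signal-intensity variation of a line profile: (max - min) / total.

    Distinguishes punctate from diffuse signal along a hand-drawn line:
    a single bright spike on a low baseline scores higher than the same
    total intensity spread evenly.
    """
    values = np.asarray(profile, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise SamQuantError("intensity_variation needs >= 2 ordered samples")
    total = float(values.sum())
    if total <= 0:
        raise SamQuantError("intensity_variation: total signal must be > 0")
    return float((values.max() - values.min()) / total)
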