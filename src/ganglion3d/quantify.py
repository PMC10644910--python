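"""Per-cell morphometric and intensity quantification.

Each segmented object is measured in the original raw channels (never in
thresholded data): voxel and physical volume, centroid, bounding box,
principal-axis lengths with the derived shape features, a sphericity
estimate, and {mean, sum, min, max, std} of every raw channel over the
object's voxels.  Stack-level summaries (percent volume, count, count
per mm^3) support either the whole imaged stack or the tissue region as
denominator, since whole-mount fields contain empty mountant.

Principal axes are computed in physical (µm) coordinates so anisotropic
z-spacing does not distort shape.  The voxel-coordinate covariance gets
a per-voxel box correction (spacing^2/12 on the diagonal — voxels are
little boxes, not points), which keeps one-voxel-thin objects at finite
axis ratios; eigenvalues map to full axis lengths by the uniform-solid-
ellipsoid convention, axis = 2*sqrt(5*lambda).  Surface area for
sphericity is estimated by counting exposed voxel faces weighted by
their physical areas; this voxelization-biased estimator overstates the
area of smooth surfaces (a sphere by ~a factor 1.5), so sphericity is
comparable between objects but is not an absolute geometric measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .classify import CLASS_FRR, CLASS_NSRR, CLASS_UNCLASSIFIED, ObjectClassification
from .imgio import BACKGROUND, InstanceLabelMap, MultiChannelStack, RegionMap

SHAPE_FEATURES = ("elongation", "flatness", "ellipticity", "sphericity")

#: fixed leading columns of the cell table; per-channel stat columns
#: (``{channel}_{stat}``) follow in channel order.
BASE_COLUMNS = [
    "source_name", "object_id", "cell_class",
    "volume_vox", "volume_um3",
    "centroid_z_vox", "centroid_y_vox", "centroid_x_vox",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "bbox_zmin", "bbox_ymin", "bbox_xmin", "bbox_zmax", "bbox_ymax", "bbox_xmax",
    "axis_a_um", "axis_b_um", "axis_c_um",
    "elongation", "flatness", "ellipticity", "sphericity",
]
CHANNEL_STATS = ("mean", "sum", "min", "max", "std")


def principal_axis_lengths(coords_um: np.ndarray, spacing) -> tuple[float, float, float]:
    """Full principal-axis lengths (µm) of a voxel cloud, a >= b >= c."""
    centered = coords_um - coords_um.mean(axis=0)
    cov = centered.T @ centered / len(coords_um)
    cov += np.diag(np.square(spacing) / 12.0)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    a, b, c = (2.0 * np.sqrt(5.0 * eigvals)).tolist()
    return a, b, c


def surface_area_um2(obj_mask: np.ndarray, spacing) -> float:
    """Exposed-face surface area of a boolean object grid, in µm²."""
    dz, dy, dx = spacing
    face_area = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    padded = np.pad(obj_mask, 1)
    total = 0.0
    for axis, area in face_area.items():
        diff = np.diff(padded.astype(np.int8), axis=axis)
        total += float(np.abs(diff).sum()) * area
    return total


def quantify_objects(
    m: InstanceLabelMap,
    stack: MultiChannelStack,
    c: ObjectClassification | None = None,
) -> pd.DataFrame:
    """Build the per-cell table: one row per object, ordered by object id.

    ``c`` may be None (no region map in the run), in which case every
    object is annotated UNCLASSIFIED; classification columns are always
    present so combined spreadsheets from mixed runs align.
    """
    if m.labels.shape != stack.shape:
        raise ValueError(f"label map shape {m.labels.shape} != stack shape {stack.shape}")
    ids = m.object_ids
    if c is not None:
        missing = set(ids.tolist()) - set(c.classes)
        if missing:
            raise ValueError(f"objects without classification: {sorted(missing)}")

    spacing = np.asarray(m.spacing, dtype=np.float64)
    voxel_volume = float(np.prod(spacing))
    rows: list[dict] = []
    slices = ndi.find_objects(m.labels)
    for obj_id in ids.tolist():
        sl = slices[obj_id - 1]
        local = m.labels[sl] == obj_id
        coords_vox = np.argwhere(local) + [s.start for s in sl]
        n_vox = len(coords_vox)
        coords_um = coords_vox * spacing
        centroid_vox = coords_vox.mean(axis=0)
        a, b, c_len = principal_axis_lengths(coords_um, spacing)
        area = surface_area_um2(local, spacing)
        volume_um3 = n_vox * voxel_volume
        sphericity = float(np.pi ** (1 / 3) * (6 * volume_um3) ** (2 / 3) / area)

        row = {
            "source_name": stack.source_name,
            "object_id": obj_id,
            "cell_class": c.class_of(obj_id) if c is not None else CLASS_UNCLASSIFIED,
            "volume_vox": n_vox,
            "volume_um3": volume_um3,
            "centroid_z_vox": centroid_vox[0],
            "centroid_y_vox": centroid_vox[1],
            "centroid_x_vox": centroid_vox[2],
            "centroid_z_um": centroid_vox[0] * spacing[0],
            "centroid_y_um": centroid_vox[1] * spacing[1],
            "centroid_x_um": centroid_vox[2] * spacing[2],
            "bbox_zmin": sl[0].start, "bbox_ymin": sl[1].start, "bbox_xmin": sl[2].start,
            "bbox_zmax": sl[0].stop, "bbox_ymax": sl[1].stop, "bbox_xmax": sl[2].stop,
            "axis_a_um": a, "axis_b_um": b, "axis_c_um": c_len,
            "elongation": a / b,
            "flatness": b / c_len,
            "ellipticity": 1.0 - c_len / a,
            "sphericity": sphericity,
        }
        for name, channel in stack.channels.items():
            values = channel[sl][local].astype(np.float64)
            row[f"{name}_mean"] = values.mean()
            row[f"{name}_sum"] = values.sum()
            row[f"{name}_min"] = values.min()
            row[f"{name}_max"] = values.max()
            row[f"{name}_std"] = values.std()
        rows.append(row)

    columns = BASE_COLUMNS + [
        f"{name}_{stat}" for name in stack.channels for stat in CHANNEL_STATS
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(["source_name", "object_id"], kind="stable").reset_index(drop=True)


@dataclass
class StackSummary:
    """Stack-level readouts for one cell class (or all cells)."""

    source_name: str
    cell_class: str
    count: int
    volume_vox: int
    percent_volume: float
    count_per_mm3: float
    denominator_mode: str


def summarize_stack(
    m: InstanceLabelMap,
    table: pd.DataFrame,
    denominator_mode: str = "stack",
    region: RegionMap | None = None,
) -> pd.DataFrame:
    """Percent volume and count density per class and overall.

    ``stack`` uses every voxel of the imaged stack as denominator;
    ``tissue`` restricts to NSRR+FRR voxels (requires a region map).
    """
    if denominator_mode not in ("stack", "tissue"):
        raise ValueError(f"denominator mode must be 'stack' or 'tissue', got {denominator_mode!r}")
    if denominator_mode == "tissue":
        if region is None:
            raise ValueError("tissue denominator requires a region map")
        denom_vox = int((region.regions != BACKGROUND).sum())
    else:
        denom_vox = int(m.labels.size)
    voxel_volume_um3 = float(np.prod(m.spacing))
    denom_mm3 = denom_vox * voxel_volume_um3 * 1e-9

    groups = [(cls, sub) for cls, sub in table.groupby("cell_class", sort=True)]
    groups.append(("ALL", table))
    summaries = []
    for cls, sub in groups:
        count = len(sub)
        vol = int(sub["volume_vox"].sum())
        summaries.append(StackSummary(
            source_name=table["source_name"].iloc[0] if len(table) else "",
            cell_class=cls,
            count=count,
            volume_vox=vol,
            percent_volume=100.0 * vol / denom_vox if denom_vox else 0.0,
            count_per_mm3=count / denom_mm3 if denom_mm3 else 0.0,
            denominator_mode=denominator_mode,
        ))
    return pd.DataFrame([s.__dict__ for s in summaries])


def compare_shape_by_class(table: pd.DataFrame, feature: str = "elongation") -> pd.DataFrame:
    """Per-class mean/median/sd of one shape feature.

    Statistical testing is deliberately left to the caller — the cell
    table exports cleanly to any stats environment.
    """
    if feature not in SHAPE_FEATURES:
        raise ValueError(f"unknown shape feature {feature!r}; choose from {SHAPE_FEATURES}")
    out = (
        table.groupby("cell_class")[feature]
        .agg(n="count", mean="mean", median="median", sd="std")
        .reset_index()
    )
    out.insert(1, "feature", feature)
    return out


def per_object_channel_intensity(table: pd.DataFrame, channel_name: str) -> pd.DataFrame:
    """Project one channel's per-object mean intensity with annotations.

    The tracer-uptake readout (e.g. mean dextran within each macrophage)
    is exactly this projection.
    """
    col = f"{channel_name}_mean"
    if col not in table.columns:
        known = sorted({c.rsplit("_", 1)[0] for c in table.columns if c.endswith("_mean")})
        raise ValueError(f"channel {channel_name!r} not in table (has {known})")
    return table[["source_name", "object_id", "cell_class", col]].rename(
        columns={col: f"{channel_name}_mean_intensity"}
    )
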