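"""Tissue-region classification of segmented objects.

Each object is assigned NSRR (neuronal-soma-rich region), FRR
(fiber-rich region) or UNCLASSIFIED by the fraction of its voxels that
fall inside each region of a categorical region map.  The default rule
is the "50% or more" inclusion criterion: an object belongs to a region
when at least half its voxels lie there; an exact 0.5/0.5 tie (possible
only at inclusion fraction exactly 0.5) is UNCLASSIFIED, keeping the
assignment unique.  BACKGROUND overlap never counts toward a class —
objects mostly outside tissue become UNCLASSIFIED rather than being
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import BACKGROUND, FRR, NSRR, InstanceLabelMap, RegionMap

CLASS_NSRR = "NSRR"
CLASS_FRR = "FRR"
CLASS_UNCLASSIFIED = "UNCLASSIFIED"

_REGION_OF_CLASS = {CLASS_NSRR: NSRR, CLASS_FRR: FRR}


@dataclass
class ClassificationParams:
    inclusion_fraction: float = 0.5
    unclassified_policy: str = "keep"  # keep | drop

    def __post_init__(self) -> None:
        if not 0.5 <= self.inclusion_fraction <= 1.0:
            raise ValueError(
                f"inclusion fraction must lie in [0.5, 1] (values below 0.5 could "
                f"multiply-assign), got {self.inclusion_fraction}"
            )
        if self.unclassified_policy not in ("keep", "drop"):
            raise ValueError(f"unclassified policy must be 'keep' or 'drop', got {self.unclassified_policy!r}")


@dataclass
class ObjectClassification:
    """Per-object class plus the exact overlap fractions behind it."""

    classes: dict[int, str] = field(default_factory=dict)
    fractions: dict[int, dict[str, float]] = field(default_factory=dict)

    def class_of(self, object_id: int) -> str:
        return self.classes[object_id]


def region_from_probmap(
    probs: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    tissue_cutoff: float | None = None,
    tissue_mask: np.ndarray | None = None,
) -> RegionMap:
    """Derive a hard NSRR/FRR/BACKGROUND partition from an NSRR probability map.

    Voxels outside tissue become BACKGROUND; within tissue, probability
    >= 0.5 is NSRR, below is FRR.  Tissue defaults to the probability
    map's support (prob > 0); pass ``tissue_cutoff`` or an explicit
    ``tissue_mask`` to override.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 3:
        raise ValueError("probability map must be 3D")
    if tissue_mask is not None:
        if tissue_mask.shape != probs.shape:
            raise ValueError(f"tissue mask shape {tissue_mask.shape} != probmap shape {probs.shape}")
        tissue = tissue_mask.astype(bool)
    elif tissue_cutoff is not None:
        tissue = probs >= tissue_cutoff
    else:
        tissue = probs > 0
    regions = np.full(probs.shape, BACKGROUND, dtype=np.uint8)
    regions[tissue & (probs >= 0.5)] = NSRR
    regions[tissue & (probs < 0.5)] = FRR
    return RegionMap(regions=regions, spacing=spacing)


def classify_objects(
    m: InstanceLabelMap,
    r: RegionMap,
    p: ClassificationParams | None = None,
) -> ObjectClassification:
    """Assign each object a region class by fractional voxel overlap.

    For every object the exact fractions of its voxels in NSRR and FRR
    are computed (integer voxel-count ratios); the region whose fraction
    reaches the inclusion criterion wins.  At inclusion fraction > 0.5 at
    most one region can qualify; at exactly 0.5 a perfect 0.5/0.5 tie is
    UNCLASSIFIED.
    """
    p = p or ClassificationParams()
    if m.labels.shape != r.regions.shape:
        raise ValueError(f"label map shape {m.labels.shape} != region map shape {r.regions.shape}")

    result = ObjectClassification()
    ids = m.object_ids
    if ids.size == 0:
        return result

    n_bins = int(ids.max()) + 1
    flat_labels = m.labels.ravel()
    flat_regions = r.regions.ravel()
    totals = np.bincount(flat_labels, minlength=n_bins)
    in_nsrr = np.bincount(flat_labels, weights=(flat_regions == NSRR), minlength=n_bins)
    in_frr = np.bincount(flat_labels, weights=(flat_regions == FRR), minlength=n_bins)

    for obj_id in ids.tolist():
        total = int(totals[obj_id])
        f_nsrr = int(in_nsrr[obj_id]) / total
        f_frr = int(in_frr[obj_id]) / total
        if f_nsrr >= p.inclusion_fraction and f_frr >= p.inclusion_fraction:
            cls = CLASS_UNCLASSIFIED  # only reachable as an exact 0.5/0.5 tie
        elif f_nsrr >= p.inclusion_fraction:
            cls = CLASS_NSRR
        elif f_frr >= p.inclusion_fraction:
            cls = CLASS_FRR
        else:
            cls = CLASS_UNCLASSIFIED
        result.classes[obj_id] = cls
        result.fractions[obj_id] = {
            CLASS_NSRR: f_nsrr,
            CLASS_FRR: f_frr,
            "BACKGROUND": 1.0 - f_nsrr - f_frr,
        }
    return result


def split_by_class(
    m: InstanceLabelMap,
    c: ObjectClassification,
    policy: str = "keep",
) -> dict[str, InstanceLabelMap]:
    """Emit one label map per class, each object keeping its original label.

    With policy ``keep`` an UNCLASSIFIED map is emitted; with ``drop``
    unclassified objects appear in no output map.  Per-class foregrounds
    partition the (policy-filtered) input foreground.
    """
    if policy not in ("keep", "drop"):
        raise ValueError(f"policy must be 'keep' or 'drop', got {policy!r}")
    unknown = set(c.classes) - set(m.object_ids.tolist())
    if unknown:
        raise ValueError(f"classification refers to unknown object ids {sorted(unknown)}")
    missing = set(m.object_ids.tolist()) - set(c.classes)
    if missing:
        raise ValueError(f"objects without classification: {sorted(missing)}")

    wanted = [CLASS_NSRR, CLASS_FRR] + ([CLASS_UNCLASSIFIED] if policy == "keep" else [])
    out: dict[str, InstanceLabelMap] = {}
    for cls in wanted:
        members = np.array([i for i, k in c.classes.items() if k == cls], dtype=m.labels.dtype)
        labels = np.where(np.isin(m.labels, members), m.labels, 0)
        out[cls] = InstanceLabelMap(labels=labels.astype(m.labels.dtype), spacing=m.spacing)
    return out
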