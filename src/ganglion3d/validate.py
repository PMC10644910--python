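"""Expert-comparison scoring of an instance segmentation.

The reference is a 2D annotation drawn by an expert on a z-projection of
the stack; the prediction is z-projected the same way and the two label
images are matched by footprint overlap.  Four counts summarize
agreement:

* correct — expert objects in a mutual one-to-one link with a predicted
  object (percent_correct = 100 * correct / n_expert);
* incorrect — missed expert objects plus spurious predicted objects;
* under-segmented — predicted objects linked to two or more expert
  objects (several cells merged into one);
* over-segmented — expert objects linked to two or more predicted
  objects (one cell split apart).

A predicted object and an expert object are linked when their footprint
intersection covers at least ``min_overlap_frac`` of the smaller of the
two footprints — robust to the size disparity between expert dots or
outlines and filled predictions.  Expert point markers can be dilated to
disks before matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import InstanceLabelMap


@dataclass
class Projection2D:
    """2D integer label image; 0 = background."""

    labels2d: np.ndarray
    provenance: str = "max_projection"

    def __post_init__(self) -> None:
        if self.labels2d.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.labels2d.size and self.labels2d.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels2d)
        return ids[ids > 0]


@dataclass
class MatchTable:
    """Bipartite links between predicted and expert objects."""

    links: list[tuple[int, int, int]]  # (pred_id, expert_id, overlap_px)
    pred_ids: np.ndarray
    expert_ids: np.ndarray


@dataclass
class ValidationScores:
    n_expert: int
    n_predicted: int
    n_correct: int
    percent_correct: float
    n_missed: int
    n_spurious: int
    n_incorrect: int
    n_under_segmented: int
    n_over_segmented: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def z_project_labels(m: InstanceLabelMap) -> Projection2D:
    """Collapse a 3D label map to 2D: each pixel takes the label of the
    object owning the most voxels in its column; ties go to the smaller
    label."""
    nz, ny, nx = m.labels.shape
    flat = m.labels.reshape(nz, ny * nx)
    n_labels = int(m.labels.max()) + 1
    proj = np.zeros(ny * nx, dtype=m.labels.dtype)
    if n_labels > 1:
        # per-column vote count for every label; memory is n_labels * n_pixels,
        # fine at the stack sizes this tool sees (counts built column-block-wise
        # if that ever becomes a concern)
        counts = np.zeros((n_labels, ny * nx), dtype=np.int32)
        for z in range(nz):
            row = flat[z]
            nz_idx = np.flatnonzero(row)
            np.add.at(counts, (row[nz_idx], nz_idx), 1)
        counts[0] = 0
        winner = counts.argmax(axis=0)  # argmax breaks ties toward smaller label
        has_fg = counts.max(axis=0) > 0
        proj[has_fg] = winner[has_fg]
    return Projection2D(labels2d=proj.reshape(ny, nx), provenance="max_projection")


def dilate_points(labels2d: np.ndarray, radius: int) -> np.ndarray:
    """Grow point annotations into disks (per label, preserving identity).

    Overlapping disks keep the label of the nearer point; exact midpoints
    go to the smaller label.
    """
    if radius <= 0:
        return labels2d.copy()
    from scipy import ndimage as ndi

    fg = labels2d > 0
    dist, (iy, ix) = ndi.distance_transform_edt(~fg, return_indices=True)
    grown = np.where(dist <= radius, labels2d[iy, ix], 0)
    return grown.astype(labels2d.dtype)


def match_objects(
    pred: Projection2D,
    expert: Projection2D,
    min_overlap_frac: float = 0.5,
) -> MatchTable:
    """Link predicted to expert objects by fractional footprint overlap.

    Link rule: |p ∩ e| >= min_overlap_frac * min(|p|, |e|).  One
    predicted object may link several expert objects and vice versa; the
    scorer interprets those multiplicities.
    """
    if pred.labels2d.shape != expert.labels2d.shape:
        raise ValueError(
            f"prediction shape {pred.labels2d.shape} != expert shape {expert.labels2d.shape}"
        )
    if not 0 < min_overlap_frac <= 1:
        raise ValueError(f"min overlap fraction must lie in (0, 1], got {min_overlap_frac}")

    p = pred.labels2d.ravel()
    e = expert.labels2d.ravel()
    p_sizes = np.bincount(p)
    e_sizes = np.bincount(e)

    both = (p > 0) & (e > 0)
    pairs, overlaps = np.unique(
        np.stack([p[both], e[both]]), axis=1, return_counts=True
    )
    links = []
    for (pid, eid), ov in zip(pairs.T.tolist(), overlaps.tolist()):
        smaller = min(p_sizes[pid], e_sizes[eid])
        if ov >= min_overlap_frac * smaller:
            links.append((pid, eid, int(ov)))
    return MatchTable(links=links, pred_ids=pred.object_ids, expert_ids=expert.object_ids)


def score(matches: MatchTable) -> ValidationScores:
    """Compute the four detection/segmentation counts from a match table.

    "Correct" requires a mutual one-to-one link, so an under-segmented
    merge is never simultaneously counted correct — the correct and
    under-segmentation tallies stay disjoint.
    """
    pred_degree: dict[int, int] = {int(i): 0 for i in matches.pred_ids}
    expert_degree: dict[int, int] = {int(i): 0 for i in matches.expert_ids}
    for pid, eid, _ in matches.links:
        pred_degree[pid] += 1
        expert_degree[eid] += 1

    n_pred = len(pred_degree)
    n_expert = len(expert_degree)
    n_under = sum(1 for d in pred_degree.values() if d >= 2)
    n_over = sum(1 for d in expert_degree.values() if d >= 2)
    n_missed = sum(1 for d in expert_degree.values() if d == 0)
    n_spurious = sum(1 for d in pred_degree.values() if d == 0)
    n_correct = sum(
        1
        for pid, eid, _ in matches.links
        if pred_degree[pid] == 1 and expert_degree[eid] == 1
    )
    return ValidationScores(
        n_expert=n_expert,
        n_predicted=n_pred,
        n_correct=n_correct,
        percent_correct=100.0 * n_correct / n_expert if n_expert else 0.0,
        n_missed=n_missed,
        n_spurious=n_spurious,
        n_incorrect=n_missed + n_spurious,
        n_under_segmented=n_under,
        n_over_segmented=n_over,
    )


def score_maps(
    pred: Projection2D,
    expert: Projection2D,
    min_overlap_frac: float = 0.5,
    point_radius: int = 0,
) -> ValidationScores:
    """Convenience wrapper: optional point dilation, matching, scoring."""
    if point_radius > 0:
        expert = Projection2D(
            labels2d=dilate_points(expert.labels2d, point_radius),
            provenance=expert.provenance,
        )
    return score(match_objects(pred, expert, min_overlap_frac))
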